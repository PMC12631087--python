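# Methods

## The model

pseudokit treats pseudonymization as three coupled problems:

1. **Generation** — turning an opaque identifier into a pseudonym under a
   domain's configuration (algorithm, alphabet, length, prefix, check digit,
   salt, retries).
2. **Management** — keeping the identifier↔pseudonym links in hierarchical
   domains whose configuration is inherited, overwritten and propagated, and
   whose validity periods can revoke links (e.g. consent withdrawal).
3. **Accountability** — persisting every link and every access transactionally
   with an audit trail.

### Fill-success probability

A domain generating uniform random pseudonyms over a namespace of `k` slots,
with `n` already taken, draws a fresh pseudonym with probability
`P_new(n) = (k-n)/k`; with `m` retries a draw succeeds with
`P_attempts(n) = 1 - (n/k)^m`; and filling the domain with `q` pseudonyms
succeeds with

    P_successful(q, k, m) = prod_{n=0}^{q-1} [1 - (n/k)^m]

(draws are independent and uniform; each failed attempt within a draw hits
the same occupancy `n`). Sizing inverts this: the smallest `k >= q` with
`P_successful > T`, and the pseudonym length `l = ceil(log_a k)`. The two
definitions of `l` (via minimal `k`, or directly as the smallest `l` with
`P_successful(q, a^l, m) > T`) agree because `P_successful` is nondecreasing
in `k`; the test suite asserts this equivalence on the published grid.

## Numerical choices

* **Log-space products.** `P_successful` is evaluated as a sum of
  `log1p(-(n/k)^m)`, never as a raw float product, so near-1 probabilities
  don't lose the information in their distance from 1.
* **Power-sum path for large q.** For `q > 10^6` the direct loop is replaced
  by the exact series `log P = -sum_{j>=1} S_{jm}(q-1) / (j k^{jm})`, where
  `S_p(N) = sum n^p` is computed exactly with big integers via Faulhaber's
  formula (Bernoulli-number recurrence, cached). Terms decay like
  `((q-1)/k)^{jm}`; in every sizing regime of interest the second term is
  already below 1e-15, and the series is truncated when a term falls below
  1e-16 of the running total (accumulated as exact rationals, converted to
  float only at the end). Should the series converge too slowly (k barely
  above q), the code falls back to a chunked direct sum. Both paths agree to
  better than 1e-12 relative error on overlapping ranges (asserted in tests).
* **Threshold comparison.** The condition is the strict `P > T`, compared in
  log space; for `q <= 64` an exact rational product is used instead so the
  hand-checkable small cases (e.g. smallest `k` for `q=2, m=1, T=0.5` is 3,
  not 2) are decided without float ties. No epsilon slack is added anywhere.
* **Capacity search.** A first-order analytic seed
  `k0 = (S_m(q-1) / -ln T)^(1/m)` (slightly optimistic, hence a failing lower
  bound in practice) is bracketed by exponential stepping and finished by
  binary search — the conceptual scan over all `k >= q` is never
  materialised. `l >= 1` is enforced even when the minimal capacity is 1.
* **Monte-Carlo validation.** `simulate_fill` replays the draw-with-retries
  process literally against a `numpy` generator; the empirical success
  frequency is compared with the closed form under binomial confidence
  bounds (10^4 runs at k=200, q=50, m=2 in the acceptance suite, 2×10^5 runs
  of the permutation case k=q=10, m=1 in the unit suite).

## Generation details

* **Salting.** Hash algorithms digest the UTF-8 bytes of
  `identifier + salt`. The concatenation order is fixed and documented so
  results are reproducible; salts are generated per domain (32 hex chars from
  the OS entropy pool) and are *not* inherited by subdomains, so the same
  identifier maps to unlinkable pseudonyms in different domains. The
  salt-overwrite operation is allowed only on empty domains.
* **Hash variants.** SHA2 means SHA-256, SHA3 means SHA3-512, BLAKE3 uses its
  standard 256-bit output, xxHash the 64-bit variant — spanning digests of
  16 to 128 hex characters (64-512 bits). BLAKE3 and xxHash64 are implemented
  in-package (pure Python, full chunk/tree construction for BLAKE3) because
  no binding is available in the runtime environment; both are pinned to
  digests from an independent reference implementation in the test suite.
* **Formatting.** Padding is on the left with the configured padding
  character; cutting keeps the leftmost characters; the Luhn mod N check
  character is computed over the prefix-less body (the prefix is routing
  metadata). Hash outputs are padded/cut or check-suffixed only when length
  or check digits were *explicitly* configured for the domain — raw digests
  feed automated pipelines, short check-digited codes are for humans. The
  explicitness markers inherit together with their attributes.
* **Counters.** The consecutive algorithm counts per domain starting at 1;
  the counter state is never inherited. A value that no longer fits the
  configured width is a counter-overflow error, never a truncation.
  Consecutive pseudonyms can leak temporal ordering; the CLI warns when such
  a domain is created.
* **Retries.** Random algorithms draw at most `m` candidates against the
  domain's uniqueness constraint and fail with an exhausted-retries error;
  hash and counter algorithms are deterministic/sequential and attempted
  once (an occupied hash candidate for a different identifier is a
  hash-collision error).
* **Randomness.** Production draws come from the OS entropy pool
  (`secrets`); a seedable `random.Random` can be injected for reproducible
  tests and demos.

## Inheritance semantics

Attribute values are *materialised* in every domain: a child stores the
value it inherited together with a flag. Updates flag the target attribute
as overwritten; with propagation requested, the new value descends
recursively, but only into children (and pseudonym records, for the validity
bounds) whose flag for that attribute is still inherited — an overwritten
descendant blocks its entire subtree for that attribute. The two validity
bounds inherit independently, both at domain and at record level, so a
record can track its domain's end date while fixing its own start date (its
creation time). Without propagation an update is strictly local; consistency
between a parent and its inheriting children is therefore a property of
propagated updates, which is what the closure property test exercises.

Deletion requires an empty leaf (no child domains, no records) — cascade
semantics are deliberately not offered. Changing generation attributes on a
domain that already holds pseudonyms affects only future generation;
existing records are never rewritten.

## Storage, audit, concurrency

sqlite (single file or in-memory) holds the three-table star schema with
explicit `*_inherited` flag columns. A single serialized connection guarded
by a re-entrant lock gives linearizable operations under threads; batch
operations use per-item savepoints inside one outer transaction so a failing
item reports an error without discarding its siblings, while each item still
gets its own audit event. Audit events are written in the same transaction
as their operation (rollback removes both); failed operations — including
failed lookups — are audited afterwards with the error code as outcome.
Creating a pseudonym is idempotent per (domain, identifier), so re-running a
batch is safe. Timestamps are UTC; validity comparisons are half-open
`[start, end)`. Audit retention is enforced by an explicit purge operation
that is itself logged.

## Service and bench

The Table-style endpoint surface is an in-process dispatcher rather than an
HTTP listener; the request/response contract (path templates, methods,
status mapping, JSON/plain-text negotiation) is identical, and any token →
principal authenticator can front it. Authorization is exact-match on
`/<action-class>/<domain>` group paths; rights deliberately do not inherit
down the domain tree. The linked-pseudonym query builds the link closure
(shared identifier within the common-ancestor subtree, plus
parent-pseudonym-used-as-child-identifier chains) with a union-find and
distinguishes "no common ancestor" from "unknown source pseudonym" in its
not-found payload.

The bench driver samples operations i.i.d. from preset mixes (mostly-read
0.23/0.75/0.01/0.01, mostly-write 0.75/0.23/0.01/0.01, read-write
0.49/0.49/0.01/0.01, and a pure ping baseline), targets reads/updates/
deletes at a client-side pool of live pseudonyms, counts only successful
requests as transactions, and reports per-second TPS plus sliding-window
means (window 60 s by default, configurable; test runs use 1-2 s windows and
durations). Absolute TPS is a property of the host and is reported, never
asserted.

## What the synthetic workloads do and do not show

All test inputs are generated in-process: synthetic identifiers, random
domain trees, seeded draws. They exercise the full semantics (inheritance,
propagation, uniqueness, audit atomicity, authorization) but not
deployment-scale properties: multi-process contention, network latency,
authentication round-trips, or storage volumes beyond a few hundred
thousand rows. Passing tests show the algorithms and contracts are correct,
not that a particular installation reaches a particular throughput.

## Known limitations

* No HTTP listener, FHIR interface, record linkage or GUI; the service layer
  is in-process and the CLI is the shell entry point.
* No error-correcting pseudonym codes and no reversible cryptographic
  (encryption-based) pseudonyms; check digits detect, they do not correct.
  For base-10 alphabets the Luhn scheme has its classical adjacent-
  transposition blind spot (the 09↔90 family), quantified in the tests.
* Single-writer storage: the embedded database serializes writers; a
  server-grade SQL backend would be a schema-compatible drop-in but is not
  shipped.
* Audit events are immutable but not cryptographically signed.
* Domain renaming and cascade deletion are unsupported by design.
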