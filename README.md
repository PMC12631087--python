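# pseudokit

A pseudonymization engine for health and research data. pseudokit generates
and manages pseudonyms in hierarchical, attribute-inheriting *domains*,
persists the protected link between identifiers and pseudonyms in a
transactional store with a complete audit trail, and sizes pseudonym
namespaces by an exact collision-probability calculation.

It is aimed at the infrastructure layer of clinical studies, registries and
data-integration centres: the place where a trusted party must replace
directly identifying data (names, case numbers, sample IDs) with protected
identifiers, keep the mapping reversible for authorized staff (e.g. to
recontact patients about incidental findings), and prove afterwards who
accessed what.

## Concepts

**Domains.** A domain is a named pseudonym space with its own generation
configuration: one of nine algorithms (salted MD5 / SHA1 / SHA-256 / SHA3-512
/ BLAKE3 / xxHash64, a consecutive counter, random numbers, random strings),
an alphabet, a length, an optional prefix and Luhn mod N check digit, a retry
budget, and a validity period. Domains nest into trees — a study with visits,
a visit with data modalities — and children inherit configuration values from
their parent unless explicitly overwritten. Every inheritable attribute
carries a flag recording which case applies, and updates can be propagated
down the tree; an overwritten value blocks descent into its subtree.

**Namespace sizing.** Random pseudonyms of length *l* over an alphabet of
size *a* live in a namespace of *k = aˡ* slots. With *n* pseudonyms already
present, a draw with *m* retries succeeds with probability
*P*<sub>attempts</sub>(*n*) = 1 − (*n*/*k*)*ᵐ*, so filling the domain with
*q* pseudonyms succeeds with probability

&nbsp;&nbsp;&nbsp;&nbsp;*P*<sub>successful</sub> = ∏<sub>*n*=0</sub><sup>*q*−1</sup> [1 − (*n*/*k*)*ᵐ*].

Given a target success probability *T*, pseudokit finds the smallest
*k* ≥ *q* with *P*<sub>successful</sub> > *T* and derives
*l* = ⌈log<sub>*a*</sub> *k*⌉. New domains without an explicit length size
themselves this way automatically (defaults: *q* = 10⁸, *m* = 3,
*T* = 0.99999998, 26-letter alphabet → *l* = 10).

**Storage and audit.** A star schema — a central pseudonym table referencing
a self-referencing domain table, plus a free-standing audit table — backed by
sqlite. Every operation runs in a transaction and writes exactly one audit
event (also on failure, with the error code as outcome); a configurable
retention period bounds how long audit data is kept.

**Service surface.** The REST-style endpoint set (`/domain`,
`/domains/{domain}/pseudonym`, privileged and batch variants,
`/domains/linked-pseudonyms`, `/ping`) is exposed as an in-process dispatcher
with exact-match group-path authorization (`/record-read/bar` grants GET on
pseudonyms in domain `bar`, nothing else) and JSON-or-plain-text content
negotiation. A workload bench drives mixed create/read/update/delete
scenarios against it and reports sliding-window transactions per second.

## Worked example

```python
import random
from pseudokit import Engine, sizing
from pseudokit.store import Database

eng = Engine(Database("demo.db"), rng=random.Random(7))
study = eng.create_domain("study")
print(study.algorithm, study.alphabet.name, study.length)   # random_string letters 10

eng.create_domain("visit-1", parent="study")
print(eng.get_domain_attribute("visit-1", "algorithm"))      # ('random_string', True)

p = eng.pseudonymize("visit-1", "patient-0042")
print(p)                                                     # KEMUBCRDLSJ
print(eng.depseudonymize("visit-1", p))                      # patient-0042
print(len(eng.db.audit_events()))                            # 5

res = sizing.size_namespace(sizing.SizingRequest(q=10**8, m=3,
                                                 T=0.99999998, a=26))
print(res.k, res.l)                                          # 10772173344328 10
```

The pseudonym `KEMUBCRDLSJ` is a 10-character random string over A–Z plus a
trailing Luhn mod 26 check character; `('random_string', True)` shows the
child domain inherited the algorithm from its parent; the five audit events
are the two domain creations, the attribute read, the record creation and the
resolution. The sizing result says ~1.08 × 10¹³ slots (10 letters) suffice to
hold 10⁸ pseudonyms with 3 retries per draw at a fill-success probability
above 0.99999998.

The same flows are available from the shell:

```
$ pseudokit --db demo.db domain create registry
$ pseudokit --db demo.db pseudonymize --domain registry --id patient-0042
XLFVDUTXFBY
$ pseudokit size --q 100000000 --m 3 --alphabet-size 26
{"q": 100000000, "m": 3, "T": 0.99999998, "a": 26, "k": 10772173344328,
 "length": 10, "achieved_probability": 0.99999998}
$ pseudokit size --table          # full length grid
$ pseudokit bench --scenario mostly-read --duration 10 --threads 4
```

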