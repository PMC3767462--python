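# Subset filter definitions. Each clause: descriptor, comparator, bound(s).
# Comparators: lt, le, gt, ge, between (closed) — strictness exactly as
# printed in the standard definitions.
drug_like:
  - {descriptor: MW,   comparator: lt, bound: 500}
  - {descriptor: logP, comparator: lt, bound: 5}
  - {descriptor: HBD,  comparator: le, bound: 5}
  - {descriptor: HBA,  comparator: le, bound: 10}
lead_like:
  - {descriptor: MW,   comparator: between, lower: 150, upper: 350}
  - {descriptor: logP, comparator: le, bound: 4}
  - {descriptor: HBD,  comparator: le, bound: 3}
  - {descriptor: HBA,  comparator: le, bound: 6}
fragment_like:
  - {descriptor: MW,   comparator: le, bound: 250}
  - {descriptor: logP, comparator: between, lower: -2, upper: 3}
  - {descriptor: HBD,  comparator: lt, bound: 3}
  - {descriptor: HBA,  comparator: lt, bound: 6}
  - {descriptor: NRB,  comparator: lt, bound: 3}
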