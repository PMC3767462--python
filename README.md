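# admetprofiler

DMPK/ADMET compliance profiling for compound libraries — aimed at medicinal
chemists and cheminformaticians triaging screening collections (natural-product
libraries in particular) by predicted pharmacokinetic behaviour before any
wet-lab work.

## What it computes

Given per-compound descriptor values — either computed here from 3D structures
or imported from an external predictor's export — the package answers the
standard early-discovery questions:

* **Formula-defined descriptors** from geometry: molecular weight; H-bond
  acceptor/donor counts (HBA/HBD); rotatable bonds (NRB); solvent-accessible
  surface area *S*<sub>mol</sub> and its hydrophobic portion
  *S*<sub>mol,hfob</sub> (1.4 Å probe, per-atom sphere sampling on a
  deterministic lattice); solvent-accessible volume *V*<sub>mol</sub> (grid
  integration); globularity Glob = 4π*r*²/*S*<sub>mol</sub> with *r* the
  equal-volume-sphere radius; cohesion index
  Ind<sub>coh</sub> = HBA·HBD/*S*<sub>mol</sub>.
* **#stars compliance score**: the number of a compound's descriptors falling
  outside the ranges spanned by 95% of known drugs (e.g. *S*<sub>mol</sub>
  300–1000 Å², log*S*<sub>wat</sub> −6.0…0.5, Glob 0.75–0.95, logHERG > −5).
  A compound with #stars = 0 is fully compliant. Range panels are editable
  YAML data, not code.
* **Subset filters** with exact printed strictness: drug-like (MW < 500,
  log*P* < 5, HBD ≤ 5, HBA ≤ 10), lead-like (150 ≤ MW ≤ 350, log*P* ≤ 4,
  HBD ≤ 3, HBA ≤ 6), fragment-like (MW ≤ 250, −2 ≤ log*P* ≤ 3, HBD < 3,
  HBA < 6, NRB < 3), and Jorgensen's Rule of Three for oral availability
  (log*S*<sub>wat</sub> > −5.7, Caco-2 > 22 nm/s, #metab < 7).
* **PK decision rules**: similarity-adjusted prediction
  *P*<sub>pred</sub> = *S*·*P*<sub>exp</sub> + (1−*S*)·*P*<sub>QP</sub> for a
  query whose Tanimoto similarity *S* to its nearest training-set analogue
  reaches 0.9 (below that, the model value is kept); maximum transdermal rate
  *J*<sub>m</sub> = *K*<sub>p</sub>·MW·*S*<sub>wat</sub> with the
  *J*<sub>m</sub> > 100 flag; the CNS-activity flag (score > 1 on the −2…+2
  scale); qualitative oral-absorption binning.
* **Library summaries**: per-descriptor means, percent-compliance tables per
  subset, #stars distributions and binned histograms, rendered as
  CSV/JSON/Markdown.

QSPR-modelled descriptors (log*S*<sub>wat</sub>, Caco-2, MDCK, logHERG,
log*K*<sub>p</sub>, log*K*<sub>HSA</sub>, #metab, …) are *imported columns* —
the package maps common export headers (including the QikProp dialect:
`QPlogS`, `QPPCaco`, `#stars`, …) onto a canonical registry but deliberately
does not re-implement proprietary regressions.

A synthetic-library generator produces descriptor tables with configurable
marginals, correlations and *exactly planted* compliance fractions, so every
pipeline stage is testable end to end without external data.

## Worked example

Generate a 1,000-compound synthetic library in which exactly 70% of the
compounds are inside the aqueous-solubility range and exactly 48% are fully
compliant, then score and summarise it:

```bash
admetprofiler simulate --n 1000 --seed 42 \
    --planted "logS_wat=0.70" --stars0-fraction 0.48 --out library.csv
admetprofiler comply    --input library.csv --out compliance
admetprofiler subset    --input library.csv --out labels.csv
admetprofiler summarize --input library.csv --out report
```

`compliance/compliance.csv` begins:

```
descriptor,percent_in_range,n_present
S_mol,78.00,1000
S_mol_hfob,100.00,1000
V_mol,100.00,1000
logS_wat,70.00,1000
logK_HSA,100.00,1000
```

The planted log*S*<sub>wat</sub> fraction is recovered exactly (70.00%).
`S_mol` reads 78.00% because the generator uses it as the violation carrier
for non-compliant compounds that are not already out of range on a planted
descriptor (520 non-compliant compounds = 300 solubility violators + 220
surface-area violators). `report/report.json` carries the library summary:
1,000 compounds, 480 with #stars = 0 (48.0%), 100% with #stars ≤ 2, mean
MW 426.55 Da, mean log*P* 3.86 — the heavier, more lipophilic profile typical
of natural products. `labels.csv` classifies 476 compounds drug-like, 61
lead-like and 412 Rule-of-Three compliant under this recipe.

To profile real structures instead:

```bash
admetprofiler profile --input compounds.sdf --format sdf --out descriptors.csv
admetprofiler comply  --input descriptors.csv --out compliance
```

or, with an external predictor's export,
`admetprofiler comply --input qikprop.csv --dialect qikprop_export …`.

## Library API

Everything the CLI does is a thin layer over the importable modules:
`chem_io` (structures, tables, registry), `descriptors` (geometry/count
descriptors), `compliance` (#stars engine), `subset_rules`, `pk_rules`,
`profiling` (summaries/histograms/reports) and `synthetic_data`. See
`docs/methods.md` for the underlying models, conventions and limitations.
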