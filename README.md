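# genosensor

Label-free mutation genotyping from surface plasmon resonance (SPR) and
quartz-crystal microbalance with dissipation (QCM-D) hybridization data.

The package models the hybridization of an immobilized oligonucleotide probe
with a target DNA fragment as ideal 1:1 Langmuir binding, simulates and fits
SPR sensorgrams to recover association/dissociation rate constants
(`ka`, `kd`) and the derived equilibrium constants (`Kd = kd/ka`,
`Ka = 1/Kd`), and calls mutation status by an equilibrium-constant threshold
rule: a sample is positive when its `Ka` against the mutation-specific probe
is at most one order of magnitude below the `Ka` of the fully complementary
synthetic reference target. A parallel gravimetric route simulates QCM-D
frequency/dissipation traces and calls samples by comparing the slope of the
dissipation-versus-frequency relation against a reference curve. Cohort-level
specificity and selectivity (sensitivity) are computed with ambiguous calls
counted as incorrect.

## Layout

| module | contents |
| --- | --- |
| `genosensor.oligo` | probe/target strands, position-wise complementarity, duplex classification |
| `genosensor.spr` | 1:1 kinetics closed forms, sensorgram simulation, global least-squares fitting |
| `genosensor.qcmd` | QCM-D trace simulation, Sauerbrey mass, dissipation/frequency slope segmentation and calls |
| `genosensor.genotyping` | Ka-threshold rule, specificity/selectivity, packaged-table reproduction |
| `genosensor.cohort` | synthetic truth-labelled cohort generation and end-to-end studies |
| `genosensor.io` | CSV/FASTA/YAML dialects and the study configuration |
| `genosensor.datasets` | checksummed packaged reference tables (oligos, primers, kinetic constants, outcomes) |

## CLI

```bash
genosensor simulate --n-carriers 17 --n-noncarriers 5 --seed 1 --out cohort/
genosensor fit --input cohort/S001_spr.csv --concentration 1e-7 --out fit.csv
genosensor classify --fits fits.csv --out calls.csv
genosensor qcmd-analyze --input sample_qcmd.csv --reference ref_qcmd.csv --out call.csv
genosensor evaluate --n-carriers 17 --n-noncarriers 5 --seed 1 --out study.json
genosensor reproduce-paper --out report.json
```

All commands accept `--seed`, `--config` (YAML/JSON, see
`genosensor.io.StudyConfig`) and `--out`; outputs are deterministic for a
fixed seed and embed the package version and config hash.

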