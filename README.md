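# costimsplice

Differential alternative-splicing analysis for donor-replicated T cell
stimulation experiments — specifically, the question of how CD28
costimulation reshapes the splicing response that TCR (CD3) engagement
induces in primary human CD4+ T cells.

The package is aimed at computational biologists analysing splice-junction
read counts from a paired design (donors × stimulation arms × timepoints).
It provides, as a library and a CLI:

* **PSI/dPSI posteriors** — percent spliced-in Ψ estimated per sample with
  a beta posterior on junction-averaged counts, and for each stimulated
  arm the difference ΔΨ = Ψ_stim − Ψ_unstim together with the posterior
  probability P(|ΔΨ| ≥ 0.10);
* **reproducibility calls** — an event is significant for a condition and
  timepoint when |ΔΨ| > 10% with P(|ΔΨ| ≥ 10%) > 0.95 in ≥ 2 of 3 donors;
* **temporal trajectory classes** — Early/Transient (significant at 8 h,
  > 2-fold |ΔΨ| decay by 48 h), Early/Sustained (≤ 2-fold decay), Late;
* **the costimulation-enhancement ratio** — ΔΨ(CD3/CD28) / ΔΨ(CD3) with
  sub-1% denominators floored at 1%; ratio > 2 with concordant signs
  defines a CD28-enhanced event;
* **expression-side rules** — |log2FC| > 1.5 differential-expression
  calls, splicing/expression overlap, and RBP-encoding genes expressed at
  least twice as highly under costimulation;
* **motif windows and k-mer enrichment** — 250 nt flanking-intron windows
  around cassette exons (minus 30 nt acceptor-side and 7 nt donor-side
  splice-site exclusions), exact hypergeometric k-mer enrichment with an
  E-value < 0.05 and ratio > 2 cutoff, and IUPAC matching of enriched
  k-mers to RBP consensus sites;
* **a synthetic-data generator** that plants all of the above (null,
  TCR-driven and CD28-enhanced events with known ratios, trajectories and
  motifs) so every stage is testable with known ground truth.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Simulate a 500-event, 3-donor experiment and run the full pipeline:

```bash
costimsplice run-all --seed 7 --n-events 500 --out demo
```

```
report written to demo/report.json
significant events: {'CD28_8h': 0, 'CD28_48h': 1, 'CD3_8h': 34, 'CD3_48h': 46,
                     'CD3CD28_8h': 49, 'CD3CD28_48h': 64}
```

The report (`demo/report.json`) contains, among other things:

```json
"temporal_class_counts": {"EARLY_SUSTAINED": 29, "EARLY_TRANSIENT": 20, "LATE": 45},
"enhanced_fraction":     {"48h": 0.21875, "8h": 0.326531}
```

Reading these numbers: of the 500 simulated events, 64 were called
significantly spliced under CD3/CD28 at 48 h by the 2-of-3 donor rule
(CD28 alone induces essentially nothing, as planted). Among events
significant at either timepoint, Late changes dominate (45), followed by
Early/Sustained (29) and Early/Transient (20). At 8 h, 33% of significant
events have a CD3/CD28-to-CD3 ΔΨ ratio above 2 — i.e. their splicing
change is markedly amplified by costimulation — falling to 22% by 48 h.
Donor concordance for CD3/CD28 at 48 h is high (pairwise Pearson r
0.91–0.92 over significant events), and ~31% of significant events are
annotated as complex (non-binary) variations, matching the simulated
composition.

The same stages are available individually (`simulate`, `quantify`,
`call`, `classify`, `ratio`, `enrich`, `report`) and as library functions:

```python
from costimsplice import estimate_psi, compute_dpsi, JunctionCountRecord

stim = estimate_psi(JunctionCountRecord("ev1", "d1", "CD3", 8, [45, 41], [55]))
unstim = estimate_psi(JunctionCountRecord("ev1", "d1", "UNSTIM", 8, [20, 22], [80]))
d = compute_dpsi(stim, unstim)      # d.dpsi_hat = 0.2286, d.prob_exceeds = 0.9766
```

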