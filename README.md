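# netwin

Therapeutic-window estimation from weighted-sum Boolean models of signaling
networks, for computational/systems biologists studying heterogeneous drug
response in cancer.

A patient or cell line is represented not by its tissue of origin but by a
*differentially wired network*: its functional genomic alterations clamp
nodes of a reference signaling network constantly ON (`A`), constantly OFF
(`I`), or leave them input-dependent (`N`). Drugs are simulated as
probabilistic inhibition of nodes or of individual links, and the dose
dimension — the per-step inhibition probability `x ∈ [0, 1]` — yields a full
dose–response curve per network, from which efficacy, potency, toxicity and
the therapeutic window are read off. Minimal alteration sets that dominantly
fix a network's response ("critical determinants") and their dominance
hierarchy stratify cohorts by predicted response.

## Model

Each node `i` has a binary state `s_i`, an integer basal level `b_i`; each
link `j → i` an integer weight `w_ij`. Synchronous update:

    s_i(t+1) = 1   iff   Σ_j w_ij · s_j(t) + b_i > 0

with `A`/`I` clamps, scenario input clamps (e.g. DNA damage ON/OFF), and
per-step drug suppression applied on top (suppression wins). A trajectory is
*cell death* when the death readout's activity — its mean state over a
100-step steady window after a 100-step transient — exceeds 0.9. The
response at dose `x` is the fraction of initial states whose trajectory
dies; sweeping `x = 0, 0.1, …, 1` and shifting the dose-0 value to zero
gives the curves `f(x)` (cancer network) and `g(x)` (control network).

Scalar metrics: efficacy `max f`; potency `IC50` by linear interpolation of
the first 0.5-crossing (1 when efficacy < 0.5); toxicity `max g`; trapezoid
`AUC`; therapeutic window `sMTD − sMED`, the doses where `g` resp. `f` first
reach 0.25; combination index `CI = IC50_AB/IC50_A + IC50_AB/IC50_B`.
Responses are classified into twelve categories: selective control S1–S4
(node and/or link inhibition effective, efficacy > 0.8) × optimal control
O1–O3 (toxicity test `max f − max g > 0.5`, else potency test
`f(x) − g(x) > 0.5` at some dose, else no window); (S1–S3, O1–O2) are
desirable (D) responses.

For stratification, every subset of a network's alterations is simulated;
the *critical determinant* is the common, minimal alteration set among the
subnetworks whose (efficacy, IC50) point lies within Euclidean distance 0.1
of the full network's point. Simulating unions of one desirable and one
undesirable determinant orders them into a multi-level dominance hierarchy;
a profile's predicted response is that of its highest-level determinant
(control response when it has none).

The packaged 16-node p53-like network (`netwin/data/p53_synthetic.tsv`) is a
hand-built **synthetic stand-in** over the canonical p53 pathway players
(ATM, CHK2, p53, WIP1, MDM2, MDMX, CYCG, PTEN, AKT, p21, CYCE, E2F1, BCL2,
BAX, CASP3, plus the DNA-damage input); its weights and basal levels are
designed, not measured. Its six designated drug-target nodes
(AKT, BCL2, CYCE, MDM2, WIP1, ATM) carry 27 outgoing links, so the full
screening set — 6 node singles, 27 link singles, 15 node pairs, 297 link
pairs, 135 node–link pairs — totals 480 perturbations.

## Worked example

`python examples/02_dose_response.py` — AKT inhibition in a cancer network
carrying a BCL2-inactivating alteration, against the alteration-free
control:

```
dose      0.0  0.1  0.2  0.3  0.4  0.5  0.6  0.7  0.8  0.9  1.0
cancer f  0.00  0.44  0.79  0.96  0.98  0.98  0.98  0.98  0.98  0.98  0.98
control g 0.00  0.00  0.00  0.01  0.01  0.01  0.02  0.02  0.03  0.03  0.04
efficacy=0.980  IC50=0.116  AUC=0.857  toxicity=0.038
sMED=0.056  sMTD=inf  window=inf
```

The cancer network reaches near-complete cell death at low dose (high
efficacy, IC50 ≈ 0.12) while the control never crosses the 0.25 toxicity
threshold (sMTD = ∞): a wide therapeutic window, category (S1, O1).

`python examples/04_stratification.py` — on a cohort where a desirable
determinant (`bypass_act`), a dominant undesirable one (`shield_act`) and a
perfectly co-occurring passenger are confounded:

```
alterations response  level
 shield_act        U      2
 bypass_act        D      1
hierarchy-based prediction accuracy: 1.000
best of 5 enrichment markers:        0.850
```

The dominance hierarchy predicts every response; no single enrichment
marker can, because the label depends on the *combination* (bypass works
unless shield is present).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch: basin-of-apoptosis
analysis of the packaged network, the cancer-vs-control dose–response
metrics above, a scaled-down (S, O) screening census, determinant recovery
on a random network with a verified causal implant, and the
cohort-stratification comparison against the enrichment baseline. It prints
the computed summary and writes the results JSON to `--out`.
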