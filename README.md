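# ctdip

Histological scoring and validation pipeline for the **CTD-IP index** — a
logistic score that flags interstitial pneumonia biopsies whose histology
looks like connective tissue disease (CTD) rather than idiopathic disease.

Patients diagnosed with idiopathic pulmonary fibrosis (IPF) are steered
toward antifibrotic therapy and away from immunosuppression, so biopsies
that carry CTD-like features inside a usual-interstitial-pneumonia (UIP)
pattern matter clinically. The index gives pathologists of any experience
level a reproducible way to call them. This package implements the index
and everything needed to validate it on a multi-rater cohort: per-rater
scoring, unanimity consensus grouping, the morphological IPAF criterion,
inter-rater kappa agreement, clinical group comparisons, and a synthetic
cohort generator so the whole pipeline is testable without patient data.

## The index

A pathologist grades eight items, each 0 (none) to 3 (marked): fibroblastic
focus (FF), smooth muscle hyperplasia (SMH), cellular interstitial pneumonia
(CIP), dense perivascular collagen (DPVC), fat metaplasia (Fat), plasmacytic
infiltration (Plasm), lymphoid follicle with germinal center (LyGC) and
airspace fibrin (AF). The published index is

```
Z = +1.65 − 1.09·FF − 0.81·SMH − 0.85·CIP − 0.86·DPVC − 0.57·Fat
          + 0.86·Plasm + 0.64·LyGC + 2.47·AF
P = exp(Z) / (1 + exp(Z))
```

with `P > 0.5` (strict) labelling the rating **CTD-IP**. A case joins the
**CTD group** only when *every* rater's label is CTD-IP; any dissent leaves
it in the idiopathic group.

## Worked example

The bundled reference case is a UIP biopsy graded independently by four
pathologists (A–D):

```bash
python analysis/06_worked_example.py
```

```
rater A: Z = +3.17  P = 0.9597  CTD-IP
rater B: Z = +1.90  P = 0.8699  CTD-IP
rater C: Z = +2.30  P = 0.9089  CTD-IP
rater D: Z = +1.74  P = 0.8507  CTD-IP
consensus group: CTD (4/4 CTD-IP votes); consensus IPAF morphology: False
```

Every rater clears the 0.5 threshold — the lowest probability, 0.8507,
belongs to rater D — so the unanimity rule assigns the case to the CTD
group. Note the case *fails* the morphological IPAF criterion
(LyGC ≥ 2 and Plasm ≥ 2 for every rater): two raters graded LyGC below 2,
illustrating how the eight-item index recognises CTD-like biopsies that
the IPAF morphology cut misses.

The full synthetic-cohort analysis runs as a numbered sequence:

```bash
python analysis/01_simulate_cohort.py        # 94 cases × 4 raters
python analysis/02_score_index.py            # per-rating Z, P, label
python analysis/03_consensus_groups.py       # CTD vs idiopathic groups, dissent
python analysis/04_rater_agreement.py        # Fleiss' kappa per item + diagnosis
python analysis/05_compare_clinical_groups.py  # Fisher / t-test comparison table
```

Outputs land under `results/`. The same stages are available as a CLI
(`ctdip score|classify|agree|compare|simulate|report`) and as library
functions (`ctdip.score_table`, `ctdip.classify_cohort`, …).

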