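# starchmorph

Morphometric analysis of starch granules for archaeobotanical taxonomic
identification.

Starch granules preserved on ancient tools, in soils and in dental
calculus can identify the plants people processed — but only if the
granules of candidate taxa can be told apart quantitatively.  Classic
descriptors (maximum length, maximum width) overlap heavily between
related species.  This package implements a measurement pipeline built
around two shape characters that separate taxa where size cannot,
developed for two culturally significant Polynesian yams, *Dioscorea
alata* (oval granules) and *D. bulbifera* (triangular granules):

* **maximum length** `L` — the longest chord through the hilum (the
  deposition centre of the granule's growth rings);
* **maximum width** `W` — the longest chord perpendicular to the length
  axis;
* **eccentricity ratio** `ER = d(hilum, proximal end) / L ∈ [0, 0.5]` —
  how close the hilum sits to the nearer end of the length axis;
* **hilum angle** — the angle at the hilum subtended by the endpoints of
  the maximum-width chord, wide for oval granules with a moderately
  eccentric hilum, narrow for triangular granules whose hilum sits in
  the apex.

Around the measurement core the package provides: the longest-20%
subsample rule (`round_half_up(0.2·n)` granules by maximum length, the
stratum where taxon-specific features are clearest), assemblage
summaries, two-sample Kolmogorov–Smirnov comparisons of the four
variables at both strata, a per-taxon KDE reference model over
(ER, angle) with an indeterminate band for granule assignment, a
schema-mapping CSV reader for external measurement tables, and a
calibrated synthetic granule generator for both species so the entire
pipeline is testable without imagery.

## Worked example

```sh
python analysis/01_simulate_assemblages.py --seed 1   # 298 + 301 granules
python analysis/03_summarize_assemblages.py
python analysis/04_compare_species.py
python analysis/05_classify_granules.py --seed 1
```

The summary step prints reference-style tables, e.g. for *D. bulbifera*:

```
Taxon: D_bulbifera   n = 301 (20% subsample n = 60)
stratum length (um)           ER                angle (deg)   shape            lamellae fissure curved
100%    12.53-52.72 (m 30.99) 0.07-0.11 (m 0.09) 52-71 (m 59) triangular 96%   92       93      37
20%     38.66-52.72 (m 43.80) 0.07-0.11 (m 0.09) 53-69 (m 60) triangular 98%   95       98      57
```

i.e. the longest 60 of 301 granules are 38.7–52.7 µm long, almost all
triangular, with a strongly eccentric hilum (mean ER 0.09) and a narrow
mean hilum angle of 60°; fissures and proximal curves are enriched in
the long stratum.  The comparison step then prints:

```
KS comparison (D, p):
   100% length  D = 0.093  p = 0.148
   100% er      D = 1.000  p = 1.71e-130
   100% angle   D = 0.900  p = 9.17e-106
    20% length  D = 0.133  p = 0.66
    20% er      D = 1.000  p = 1.75e-26
    20% angle   D = 0.983  p = 1.27e-25
```

— the headline result: granule *size* does not separate the species
(p ≈ 0.15–0.66), while eccentricity ratio and hilum angle separate them
decisively (p ≪ 0.0001) in the full sample and in the longest-20%
stratum.  The classification step trains the (ER, angle) reference KDE
on those assemblages and assigns 100% of freshly simulated held-out
granules (100 per species) to the correct taxon.

The same steps are available as a CLI for external tables:

```sh
starchmorph summarize my_granules.csv --mapping mapping.yaml --text
starchmorph compare a.csv b.csv
starchmorph fit-reference a.csv b.csv --out model.json
starchmorph classify unknown.csv --model model.json --out calls.csv
```

where `mapping.yaml` names your table's columns, units and boolean
encoding (see `starchmorph.io.ColumnMapping`; a best-guess mapping for
the published *Dioscorea* reference deposit ships as
`DRYAD_GUESS_MAPPING`, and the deposited per-granule data are available
from Dryad at doi:10.5061/dryad.n8pk0p351).

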