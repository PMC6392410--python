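#!/usr/bin/env python
"""Regional distribution and clade-level biogeographic summaries.

Summarizes the reconstructed 292-species biogeography table: how many
species occupy the Nearctic, Neotropical, and Austral regions (and their
combinations), and per-clade latitudinal/elevational means.
"""

import json
from pathlib import Path

import pandas as pd

from hummnet import clade_summary, species_region_summary, write_biogeo
from hummnet.reconstruct import study_biogeo

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

table = study_biogeo()
write_biogeo(table, OUT / "biogeo_table.csv")

regions = species_region_summary(table)
(OUT / "region_summary.json").write_text(json.dumps(regions, indent=2))

clades = clade_summary(table)
frame = pd.DataFrame([vars(c) for c in clades])
frame.to_csv(OUT / "clade_summary.csv", index=False)

print(f"{regions['n_species']} species; "
      f"{regions['neotropical']} ({regions['pct_neotropical']:.1f}%) Neotropical, "
      f"{regions['nearctic_related']} Nearctic-related "
      f"({regions['nearctic_exclusive']} exclusive + "
      f"{regions['nearctic_and_neotropical']} shared), "
      f"{regions['austral_related']} Austral-related "
      f"({regions['austral_exclusive']} exclusive + {regions['austral_partial']} partial)")
print(f"{regions['multi_region']} species occupy two or more regions")
cols = ["clade", "n_species", "pct_nearctic", "pct_neotropical", "pct_austral",
        "diversification_center", "mean_lat_range", "mean_elev_range"]
print(frame[cols].round(3).to_string(index=False))
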