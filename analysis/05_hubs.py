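"""Group-level weighted-network rankings on the directed (GCA) matrices:
top-20 strongest connections, top-20 group-difference connections, top-5
out-strength regions, top-5 out-strength-difference regions, and the
consensus hub list (regions appearing in >= 2 of the 4 rankings).

Writes hub_report.json and hub_frequency.csv.
"""

from pathlib import Path

import pandas as pd

from common import config
from grangernet.pipeline import load_matrix, stage_hubs

cfg = config()
mdir = Path(cfg.out_dir) / "gca"
paths = sorted((mdir / "matrices").glob("*.tsv"))
normed = [load_matrix(p) for p in paths]
manifest = pd.read_csv(Path(cfg.out_dir) / "cohort" / "manifest.csv").set_index("subject_id")
groups = [str(manifest.loc[p.stem, "group"]) for p in paths]
report = stage_hubs(normed, groups, cfg)
report.write_json(mdir / "hub_report.json")
report.frequency_frame().to_csv(mdir / "hub_frequency.csv", index=False)
print("consensus hubs (frequency >= 2):", ", ".join(report.hubs) or "(none)")
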