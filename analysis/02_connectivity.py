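"""Estimate per-subject connectivity: pairwise Granger causality at the
BIC-selected lag order (directed) and Pearson correlation (undirected),
each normalized to [0, 1] by the subject's strongest connection.

Writes matrices under results/analysis/{gca,pcc}/matrices/.
"""

from pathlib import Path

from common import config
from grangernet.pipeline import load_subjects, save_matrix, stage_connectivity
from grangernet.timeseries import zscore

cfg = config()
cfg.manifest = str(Path(cfg.out_dir) / "cohort" / "manifest.csv")
cfg.labels_path = str(Path(cfg.out_dir) / "cohort" / "labels.txt")
subjects = [zscore(ts) for ts in load_subjects(cfg)]
for method in cfg.methods:
    normed, order = stage_connectivity(subjects, method, cfg)
    mdir = Path(cfg.out_dir) / method / "matrices"
    mdir.mkdir(parents=True, exist_ok=True)
    for ts, w in zip(subjects, normed):
        save_matrix(w, mdir / f"{ts.subject_id}.tsv")
    print(f"{method}: {len(normed)} matrices" + (f", BIC order {order}" if order else ""))
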