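"""Extract the 4 global + 4-per-region topology properties from each
subject's binary network (84 features for the 20-region cohort, 468 at
full 116-region scale).

Writes features.csv per method.
"""

from pathlib import Path

from common import config
from grangernet.pipeline import load_matrix, stage_features

cfg = config()
for method in cfg.methods:
    mdir = Path(cfg.out_dir) / method
    paths = sorted((mdir / "binary").glob("*.tsv"))
    nets = [load_matrix(p) for p in paths]
    feats = stage_features(nets, [p.stem for p in paths], cfg.degree_mode)
    feats.to_csv(mdir / "features.csv")
    print(f"{method}: feature table {feats.shape[0]} subjects x {feats.shape[1]} features")
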