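"""Binarize the weighted networks: scan retained-fraction candidates
0.05-0.50, pick the cost-efficiency (GCE = E - PSW) maximizer averaged
across subjects, and apply that single threshold to everyone.

Writes threshold_scan.csv and binary/ networks per method.
"""

from pathlib import Path

from common import config
from grangernet.pipeline import load_matrix, save_matrix
from grangernet.thresholding import proportional_binarize, select_threshold

cfg = config()
for method in cfg.methods:
    mdir = Path(cfg.out_dir) / method
    paths = sorted((mdir / "matrices").glob("*.tsv"))
    normed = [load_matrix(p) for p in paths]
    scan = select_threshold(normed, cfg.psw_grid)
    scan.to_frame().to_csv(mdir / "threshold_scan.csv", index=False)
    (mdir / "binary").mkdir(exist_ok=True)
    for p, w in zip(paths, normed):
        save_matrix(proportional_binarize(w, scan.selected_psw),
                    mdir / "binary" / p.name)
    print(f"{method}: selected PSW {scan.selected_psw:g} "
          f"(mean E at optimum {scan.mean_efficiency[scan.grid == scan.selected_psw][0]:.3f})")
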