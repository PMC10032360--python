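"""Magnitude arm: voxelwise GLM of BOLD on the rating regressor.

Loads the dataset written by 01_simulate.py (or regenerates it if
absent), runs detrending, first-level OLS and permutation-corrected
group inference, and writes the positive/negative cluster tables to
results/.  Cluster masks are cached under scratch/ for the overlay step.

Run from the repository root:  python analysis/02_glm_arm.py [seed]
"""

import json
import subprocess
import sys
from pathlib import Path

import numpy as np

from neurosync import io as nio
from neurosync.pipeline import AnalysisParams, prepare_regressor, run_glm_arm

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def load_fixture():
    dataset = SCRATCH / "dataset"
    if not (dataset / "ensemble" / "mask.nii.gz").exists():
        subprocess.run(
            [sys.executable, str(ROOT / "analysis" / "01_simulate.py"), str(SEED)],
            check=True,
        )
    ensemble = nio.load_ensemble(dataset / "ensemble")
    traces = nio.load_traces(dataset / "ratings.tsv")
    traits = nio.load_traits(dataset / "traits.tsv")
    params = AnalysisParams(
        tr=ensemble.tr, n_volumes=ensemble.n_volumes, n_perm=500, seed=SEED,
        covariates=("aq_total", "olife_total"), contrasts=(),
    )
    regressor, icc = prepare_regressor(traces, params)
    return ensemble, regressor, traits, params


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ensemble, regressor, traits, params = load_fixture()
    res = run_glm_arm(ensemble, regressor, None, params)
    summary = {}
    for tail in ("positive", "negative"):
        cr = res[f"clusters_{tail}"]
        nio.save_cluster_table(RESULTS / f"02_glm_clusters_{tail}.tsv", cr)
        np.save(SCRATCH / f"glm_sig_{tail}.npy", cr.significant_mask(params.alpha))
        summary[tail] = {
            "n_clusters": int(len(cr.table)),
            "n_significant": int((cr.table.p_corrected <= params.alpha).sum()),
            "largest_k": int(cr.table["size"].max()) if len(cr.table) else 0,
        }
    (RESULTS / "02_glm_summary.json").write_text(json.dumps(summary, indent=2))
    print("GLM arm cluster tables written to results/")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
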