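"""Synchronization arm: intersubject phase synchronization coupled to
the rating regressor.

Band-passes the dataset to 0.04-0.07 Hz, extracts analytic-signal
phases, computes each subject's leave-one-out phase-similarity series,
correlates it with the HRF-convolved rating, and runs the same
permutation-corrected group inference as the magnitude arm.

Run from the repository root:  python analysis/03_isps_arm.py [seed]
"""

import importlib.util
import json
from pathlib import Path

import numpy as np

from neurosync import io as nio
from neurosync.pipeline import run_isps_arm

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

spec = importlib.util.spec_from_file_location("glm_arm", ROOT / "analysis" / "02_glm_arm.py")
glm_arm = importlib.util.module_from_spec(spec)
spec.loader.exec_module(glm_arm)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ensemble, regressor, traits, params = glm_arm.load_fixture()
    res = run_isps_arm(ensemble, regressor, None, params)
    summary = {}
    for tail in ("positive", "negative"):
        cr = res[f"clusters_{tail}"]
        nio.save_cluster_table(RESULTS / f"03_isps_clusters_{tail}.tsv", cr)
        np.save(SCRATCH / f"isps_sig_{tail}.npy", cr.significant_mask(params.alpha))
        summary[tail] = {
            "n_clusters": int(len(cr.table)),
            "n_significant": int((cr.table.p_corrected <= params.alpha).sum()),
            "largest_k": int(cr.table["size"].max()) if len(cr.table) else 0,
        }
    zmax = max(float(np.nanmax(np.abs(m.in_mask()))) for m in res["coupling_maps"])
    summary["max_abs_fisher_z"] = round(zmax, 3)
    (RESULTS / "03_isps_summary.json").write_text(json.dumps(summary, indent=2))
    print("ISPS arm cluster tables written to results/")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
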