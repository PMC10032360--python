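"""Quadrant overlay: where do magnitude and synchronization converge or
diverge, and does the overlay recover the planted archetypes?

Combines the significant cluster masks cached by 02_glm_arm.py and
03_isps_arm.py into the sign-pair overlay, counts voxels per quadrant,
and scores the labels against the planted ground truth.

Run from the repository root:  python analysis/04_quadrant_overlay.py
"""

import json
from pathlib import Path

import numpy as np

from neurosync.inference import QUADRANT_LEGEND

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    needed = [SCRATCH / f"{arm}_sig_{tail}.npy"
              for arm in ("glm", "isps") for tail in ("positive", "negative")]
    missing = [p.name for p in needed if not p.exists()]
    if missing:
        raise SystemExit(
            f"run 02_glm_arm.py and 03_isps_arm.py first (missing: {missing})"
        )
    gp, gn = (np.load(SCRATCH / f"glm_sig_{t}.npy") for t in ("positive", "negative"))
    ip, inn = (np.load(SCRATCH / f"isps_sig_{t}.npy") for t in ("positive", "negative"))
    labels = np.zeros(gp.shape, dtype=np.int16)
    labels[gp & ip] = 1
    labels[gp & inn] = 2
    labels[gn & ip] = 3
    labels[gn & inn] = 4

    truth = np.load(SCRATCH / "dataset" / "ground_truth.npy")
    counts = {QUADRANT_LEGEND[c]: int((labels == c).sum()) for c in range(1, 5)}
    agreement = {
        QUADRANT_LEGEND[c]: round(float((labels[truth == c] == c).mean()), 3)
        for c in range(1, 5)
    }
    false_label_rate = round(float((labels[truth == 0] != 0).mean()), 4)
    out = {
        "quadrant_voxel_counts": counts,
        "planted_label_agreement": agreement,
        "false_label_rate_in_null": false_label_rate,
    }
    (RESULTS / "04_quadrant_summary.json").write_text(json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
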