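"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: AUC by explicit
pairwise enumeration, and planted-object bookkeeping computed directly
from simulator ground-truth masks.
"""

import numpy as np
from scipy import ndimage as ndi


def brute_force_auc(scores, labels) -> float:
    """AUC as the explicit pairwise win fraction (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (pos.size * neg.size)


def planted_retention(truth, isolated_band_mask, band):
    """Classify every planted crystal component in the band as retained/leaked.

    Components of the ground-truth crystal mask inside the band are matched
    against the pipeline's isolated-crystal 3D mask.  A confounder (any
    overlap with the structure mask) counts as *leaked* if the pipeline kept
    any of its voxels; an isolated crystal counts as *retained* if the
    pipeline kept at least half of them.

    Returns dict with n_isolated, n_retained, n_confounders, n_leaked.
    """
    zlo, zhi = band.first_slice - 1, band.last_slice
    planted = truth.crystal_mask[zlo:zhi]
    struct = truth.structure_mask[zlo:zhi]
    labels, n = ndi.label(planted, structure=np.ones((3, 3, 3), bool))
    out = {"n_isolated": 0, "n_retained": 0, "n_confounders": 0, "n_leaked": 0}
    for i in range(1, n + 1):
        m = labels == i
        kept = (m & isolated_band_mask).sum() / m.sum()
        if (m & struct).any():
            out["n_confounders"] += 1
            if kept > 0:
                out["n_leaked"] += 1
        else:
            out["n_isolated"] += 1
            if kept >= 0.5:
                out["n_retained"] += 1
    return out
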