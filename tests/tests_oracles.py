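"""Independent oracles used by the test suite (kept separate from the code paths
they check)."""

import numpy as np

from fibroquant.evg_quant import rgb_to_working


def brute_force_labels(image, model):
    """Per-pixel minimum squared-Mahalanobis classification by explicit loops.

    Ties keep the lowest class code, mirroring the documented tie-break.
    """
    x = rgb_to_working(image.pixels)
    prec = np.linalg.inv(model.covariances)
    h, w, _ = image.pixels.shape
    out = np.empty((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            best, best_d = 0, np.inf
            for k in range(5):
                d = x[i, j] - model.means[k]
                d2 = float(d @ prec[k] @ d)
                if d2 < best_d:
                    best, best_d = k, d2
            out[i, j] = best
    return out
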