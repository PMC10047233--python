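"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def brute_force_dilate(mask: np.ndarray, kernel: np.ndarray, anchor) -> np.ndarray:
    """Dilation as the literal union of mask translates, pixel by pixel."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    ar, ac = anchor
    for kr, kc in zip(*np.nonzero(kernel)):
        dr, dc = kr - ar, kc - ac
        for r, c in zip(*np.nonzero(mask)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                out[rr, cc] = True
    return out
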