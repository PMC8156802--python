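"""Small worked-example data used in the documentation and tests.

The ten-frame, five-class membership table walks through the
reliability-weighted-sum fusion rule end to end on hand-sized numbers:
frame 2 is confidently "class 2", frames 1, 3 and 6 point elsewhere, and
the eigenvector reliabilities down-weight exactly those three frames.
"""

from __future__ import annotations

import numpy as np


def example_kelm_output() -> np.ndarray:
    """A five-class KELM score vector whose true class is class 2.

    Under one-vs-rest +/-1 training the correct class scores near +1 and
    the rest near -1; this vector is a realistic noisy instance of that
    pattern, used to illustrate the membership transformation.
    """
    return np.array([-0.9, 0.2, -0.4, -0.8, -0.95])


def example_memberships() -> np.ndarray:
    """Ten five-class fuzzy decisions (rows: frames 1..10) for the fusion demo.

    Class-2 memberships were drawn from (0.1, 0.8) and all others from
    (0.1, 0.4), so most — but not all — frames favour class 2.
    """
    return np.array(
        [
            [0.23, 0.24, 0.34, 0.13, 0.40],
            [0.32, 0.71, 0.39, 0.23, 0.32],
            [0.10, 0.29, 0.19, 0.39, 0.18],
            [0.19, 0.52, 0.31, 0.26, 0.34],
            [0.14, 0.40, 0.36, 0.31, 0.13],
            [0.13, 0.33, 0.37, 0.19, 0.23],
            [0.16, 0.57, 0.13, 0.31, 0.37],
            [0.20, 0.36, 0.11, 0.35, 0.19],
            [0.22, 0.50, 0.15, 0.11, 0.19],
            [0.26, 0.58, 0.36, 0.33, 0.14],
        ]
    )


#: Reliability rescaling bounds that map the demo's eigenvector onto
#: [0.3, 1.0]; the walkthrough in the docs uses these.
EXAMPLE_REL_LOWER = 0.3
EXAMPLE_REL_SPAN = 0.7
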