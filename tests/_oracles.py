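"""Independent reference implementations used only to verify the package.

These deliberately take different algorithmic routes from the library:
plain recursion for edit distance, Horn's closed-form quaternion method
for rigid superposition.
"""

from functools import lru_cache

import numpy as np


def levenshtein_recursive(a: str, b: str) -> int:
    """Textbook recursive edit distance (memoised); fine for short strings."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return d(len(a), len(b))


def horn_rmsd(ref: np.ndarray, mov: np.ndarray) -> float:
    """Minimum RMSD via Horn's quaternion eigenvalue method."""
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    r = ref - ref.mean(axis=0)
    m = mov - mov.mean(axis=0)
    s = m.T @ r
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    n = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(n)[-1]
    sq = (np.sum(r ** 2) + np.sum(m ** 2) - 2.0 * lam) / len(ref)
    return float(np.sqrt(max(sq, 0.0)))
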