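"""Isotope distribution by elemental convolution.

Computes the isotopologue distribution of an elemental composition as the
convolution of per-element distributions, each obtained by binary-power
convolution of the single-atom isotope distribution with aggregation of
peaks closer than a fixed mass resolution and pruning of negligible
probability.  This scales to large peptides where naive fine-structure
enumeration is combinatorial, while preserving fine structure well below
typical m/z bin widths (default aggregation resolution 2e-4 Da).

Isotope masses and abundances come from the NIST table shipped with
pyteomics.  Peak positions are mass shifts relative to the monoisotopic
(all-lightest-isotope) species.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from pyteomics.mass import nist_mass

_RESOLUTION = 2e-4   # Da; aggregation grid for fine structure
_PRUNE = 1e-8        # drop peaks below this probability during convolution


def _aggregate(shifts: np.ndarray, probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge peaks on the aggregation grid (probability-weighted mass)."""
    keys = np.round(shifts / _RESOLUTION).astype(np.int64)
    order = np.argsort(keys, kind="stable")
    keys, shifts, probs = keys[order], shifts[order], probs[order]
    uniq, start = np.unique(keys, return_index=True)
    p = np.add.reduceat(probs, start)
    ws = np.add.reduceat(probs * shifts, start)
    return ws / p, p


def _convolve(a: tuple[np.ndarray, np.ndarray],
              b: tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    sa, pa = a
    sb, pb = b
    shifts = (sa[:, None] + sb[None, :]).ravel()
    probs = (pa[:, None] * pb[None, :]).ravel()
    keep = probs > _PRUNE
    shifts, probs = _aggregate(shifts[keep], probs[keep])
    return shifts, probs


@lru_cache(maxsize=None)
def _element_distribution(element: str, n: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Distribution of mass shifts for ``n`` atoms of ``element``."""
    iso = [(m, ab) for key, (m, ab) in nist_mass[element].items()
           if key != 0 and ab > 0]
    iso.sort()
    m0 = iso[0][0]
    single = (np.array([m - m0 for m, _ in iso]), np.array([ab for _, ab in iso]))
    # binary exponentiation of the single-atom distribution
    result = (np.zeros(1), np.ones(1))
    base = single
    k = n
    while k:
        if k & 1:
            result = _convolve(result, base)
        k >>= 1
        if k:
            base = _convolve(base, base)
    return tuple(result[0]), tuple(result[1])


def isotope_distribution(composition: dict[str, int],
                         prune: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """(mass shifts, probabilities) of the composition's isotopologues,
    shifts relative to the monoisotopic species, pruned below ``prune``."""
    dist = (np.zeros(1), np.ones(1))
    for element, n in sorted(composition.items()):
        if n <= 0:
            continue
        sh, pr = _element_distribution(element, int(n))
        dist = _convolve(dist, (np.array(sh), np.array(pr)))
    shifts, probs = dist
    keep = probs > prune
    order = np.argsort(shifts[keep])
    return shifts[keep][order], probs[keep][order]
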