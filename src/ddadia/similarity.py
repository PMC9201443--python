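"""Modified-cosine similarity between tandem mass spectra.

The modified cosine extends the spectral cosine by letting a fragment pair
match either *directly* (|mz_a - mz_b| <= fragment tolerance) or *shifted* by
the precursor mass difference Delta = precursor_a - precursor_b
(|mz_a - mz_b - Delta| <= tolerance). Intensities are raised to a power p
(default 0.5, square-root weighting) before normalisation, matching common
GNPS practice. The score is

    score(a, b) = max_M sum_{(i,j) in M} Ia_i^p * Ib_j^p / (||a||_p ||b||_p)

over one-to-one assignments M of candidate pairs, with ||.||_p the Euclidean
norm of p-powered intensities. Self-similarity is exactly 1 (Cauchy-Schwarz).

Production scoring uses the GNPS-style greedy assignment (descending pair
weight, ties by smaller |m/z difference| then lower peak index);
:func:`max_assignment_score` provides the exact maximum-weight assignment as
a reference for validation. Greedy never exceeds exact and coincides with it
whenever no peak has two competing candidate partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .models import SimilarityEdge, Spectrum


@dataclass
class ScoreConfig:
    """Tolerances and weighting of the modified-cosine score.

    Defaults follow the GNPS networking settings of the source study:
    fragment and parent mass tolerance 0.02 Da, square-root intensity
    weighting, precursor-shifted matching enabled.
    """

    fragment_tol: float = 0.02    # Da
    parent_tol: float = 0.02      # Da
    intensity_power: float = 0.5  # p in (0, 1]
    allow_shifted: bool = True

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0 or self.parent_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if not 0 < self.intensity_power <= 1:
            raise ValueError("intensity_power must lie in (0, 1]")


class CandidatePair(NamedTuple):
    index_a: int
    index_b: int
    weight: float     # Ia^p * Ib^p
    mz_diff: float    # |mz_a - mz_b|
    shifted: bool


def candidate_pairs(a: Spectrum, b: Spectrum,
                    cfg: ScoreConfig | None = None) -> list[CandidatePair]:
    """All peak pairs matching directly or shifted by the precursor difference.

    Shifted matching applies only when enabled and |Delta| > fragment_tol
    (otherwise it would duplicate the direct window). A pair qualifying both
    ways is emitted once, as direct.
    """
    cfg = cfg or ScoreConfig()
    if len(a) == 0 or len(b) == 0:
        return []
    p = cfg.intensity_power
    wa = a.intensities ** p
    wb = b.intensities ** p
    diff = a.mz[:, None] - b.mz[None, :]
    direct = np.abs(diff) <= cfg.fragment_tol
    mask = direct.copy()
    shift = a.precursor_mz - b.precursor_mz
    if cfg.allow_shifted and abs(shift) > cfg.fragment_tol:
        mask |= np.abs(diff - shift) <= cfg.fragment_tol
    ia, ib = np.nonzero(mask)
    return [CandidatePair(int(i), int(j), float(wa[i] * wb[j]),
                          float(abs(diff[i, j])), not direct[i, j])
            for i, j in zip(ia, ib)]


def _norms(a: Spectrum, b: Spectrum, p: float) -> float:
    na = float(np.sqrt(np.sum(a.intensities ** (2 * p))))
    nb = float(np.sqrt(np.sum(b.intensities ** (2 * p))))
    return na * nb


def greedy_assignment(pairs: list[CandidatePair]) -> list[CandidatePair]:
    """One-to-one selection by descending weight (GNPS-style greedy).

    Ties break on smaller |m/z difference|, then lower index in the first
    spectrum, then the second — fully deterministic.
    """
    chosen: list[CandidatePair] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for c in sorted(pairs, key=lambda c: (-c.weight, c.mz_diff,
                                          c.index_a, c.index_b)):
        if c.index_a not in used_a and c.index_b not in used_b:
            chosen.append(c)
            used_a.add(c.index_a)
            used_b.add(c.index_b)
    return chosen


def modified_cosine(a: Spectrum, b: Spectrum,
                    cfg: ScoreConfig | None = None) -> SimilarityEdge:
    """Greedy modified-cosine similarity between two spectra.

    Symmetric in score and matched-peak count: internally the pair is put in
    canonical (spectrum id) order before assignment, so tie-breaking cannot
    depend on argument order. Empty spectra yield score 0 with 0 matches.
    """
    cfg = cfg or ScoreConfig()
    x, y = sorted((a, b), key=lambda s: s.spectrum_id)
    shift = x.precursor_mz - y.precursor_mz
    if len(x) == 0 or len(y) == 0:
        return SimilarityEdge(x.spectrum_id, y.spectrum_id, score=0.0,
                              n_matched=0, mass_shift=shift)
    chosen = greedy_assignment(candidate_pairs(x, y, cfg))
    total = sum(c.weight for c in chosen)
    score = min(total / _norms(x, y, cfg.intensity_power), 1.0 + 1e-12)
    return SimilarityEdge(x.spectrum_id, y.spectrum_id, score=score,
                          n_matched=len(chosen), mass_shift=shift)


def max_assignment_score(a: Spectrum, b: Spectrum,
                         cfg: ScoreConfig | None = None) -> tuple[float, int]:
    """Exact maximum-weight one-to-one assignment score (reference routine).

    Solves the assignment on the candidate-pair weight matrix with the
    Hungarian algorithm; returns (score, n_matched). Used for validating the
    greedy production path — the greedy score can never exceed this one.
    """
    cfg = cfg or ScoreConfig()
    x, y = sorted((a, b), key=lambda s: s.spectrum_id)
    pairs = candidate_pairs(x, y, cfg)
    if not pairs:
        return 0.0, 0
    w = np.zeros((len(x), len(y)))
    for c in pairs:
        w[c.index_a, c.index_b] = max(w[c.index_a, c.index_b], c.weight)
    rows, cols = linear_sum_assignment(w, maximize=True)
    used = w[rows, cols]
    total = float(used.sum())
    return (min(total / _norms(x, y, cfg.intensity_power), 1.0 + 1e-12),
            int(np.count_nonzero(used)))
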