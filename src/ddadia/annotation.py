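"""Spectral-library annotation of retained features.

Candidates are library entries whose precursor m/z lies within the MS1
tolerance (default 0.01 Da) of the feature; each candidate is scored with
the modified cosine at the MS2 tolerance (default 0.025 Da) with precursor-
shifted matching disabled — identification, not analog search. Hits are
ranked per feature by MS2 score (descending), then absolute precursor error,
then name, so ranks are total and reproducible. A feature without an MS2
spectrum falls back to precursor-only candidates flagged "MS1-only"; final
structure confirmation beyond ranked candidates is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .models import (AnnotationHit, Feature, LibraryEntry, Spectrum, ppm_error)
from .similarity import ScoreConfig, modified_cosine

log = logging.getLogger(__name__)


@dataclass
class AnnotationConfig:
    ms1_tol: float = 0.01    # Da, precursor match window
    ms2_tol: float = 0.025   # Da, fragment tolerance for library scoring
    intensity_power: float = 0.5
    max_hits: Optional[int] = None  # per feature; None = all candidates

    def __post_init__(self) -> None:
        if self.ms1_tol <= 0 or self.ms2_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class AnnotationResult:
    hits: list[AnnotationHit] = field(default_factory=list)
    unannotated: list[str] = field(default_factory=list)  # zero candidates

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "feature_id": h.feature_id, "name": h.library_name,
            "score": h.ms2_score, "n_matched": h.n_matched,
            "error_da": h.precursor_error_da, "error_ppm": h.precursor_error_ppm,
            "rank": h.rank, "ms1_only": h.ms1_only,
        } for h in self.hits], columns=["feature_id", "name", "score",
                                        "n_matched", "error_da", "error_ppm",
                                        "rank", "ms1_only"])


def annotate(features: Sequence[Feature],
             spectra: Mapping[str, Spectrum],
             library: Sequence[LibraryEntry],
             cfg: AnnotationConfig | None = None) -> AnnotationResult:
    """Rank library candidates for each feature.

    ``spectra`` maps spectrum_ref (or feature id) to the feature's MS2
    spectrum; a missing spectrum degrades that feature to MS1-only hits
    ranked by precursor error alone.
    """
    cfg = cfg or AnnotationConfig()
    if not library:
        raise ValueError("library is empty")
    score_cfg = ScoreConfig(fragment_tol=cfg.ms2_tol, parent_tol=cfg.ms1_tol,
                            intensity_power=cfg.intensity_power,
                            allow_shifted=False)
    result = AnnotationResult()
    for f in features:
        cands = [e for e in library
                 if abs(f.precursor_mz - e.precursor_mz) <= cfg.ms1_tol]
        if not cands:
            result.unannotated.append(f.feature_id)
            continue
        spec = None
        for key in (f.spectrum_ref, f.feature_id):
            if key and key in spectra:
                spec = spectra[key]
                break
        scored = []
        for e in cands:
            err = f.precursor_mz - e.precursor_mz
            if spec is not None and len(spec) > 0:
                edge = modified_cosine(spec, e.as_spectrum(), score_cfg)
                scored.append((e, err, edge.score, edge.n_matched, False))
            else:
                scored.append((e, err, None, None, True))
        scored.sort(key=lambda t: (-(t[2] if t[2] is not None else -1.0),
                                   abs(t[1]), t[0].name))
        if cfg.max_hits is not None:
            scored = scored[:cfg.max_hits]
        for rank, (e, err, score, n_matched, ms1_only) in enumerate(scored, 1):
            result.hits.append(AnnotationHit(
                feature_id=f.feature_id, library_name=e.name,
                precursor_error_da=err,
                precursor_error_ppm=ppm_error(f.precursor_mz, e.precursor_mz),
                ms2_score=score, n_matched=n_matched, rank=rank,
                ms1_only=ms1_only))
    if result.unannotated:
        log.info("annotate: %d features had no candidate within %.4g Da",
                 len(result.unannotated), cfg.ms1_tol)
    return result


def rank_one_hits(result: AnnotationResult) -> dict[str, AnnotationHit]:
    """Best hit per feature."""
    return {h.feature_id: h for h in result.hits if h.rank == 1}
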