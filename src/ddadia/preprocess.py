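"""Feature- and spectrum-level filters applied before networking.

Defaults reproduce the MS-DIAL processing settings of the study this package
operationalises: retention time 0.5–35 min, MS1 mass range 100–1000 Da,
minimum peak height 2000 counts, MS/MS abundance cutoff 500 counts, MS/MS
mass range 0–1000 Da. All range bounds are inclusive and the intensity cutoff
keeps peaks with intensity >= cutoff (MS-DIAL semantics).

MS-DIAL's raw-extraction parameters (mass slice width 0.1 Da, sigma window
0.5) act upstream of the exported peak tables this package consumes; they are
recorded here for provenance only and are not reapplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .models import FeatureTable, Spectrum

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    rt_min_range: tuple[float, float] = (0.5, 35.0)   # minutes
    ms1_mass_range: tuple[float, float] = (100.0, 1000.0)  # Da
    min_peak_height: float = 2000.0                   # counts
    msms_abundance_cutoff: float = 500.0              # counts
    ms2_mass_range: tuple[float, float] = (0.0, 1000.0)    # Da
    # upstream MS-DIAL extraction parameters, provenance only:
    provenance: dict = field(default_factory=lambda: {
        "mass_slice_width_da": 0.1, "sigma_window_value": 0.5,
        "alignment_rt_tolerance_min": 0.05})

    def __post_init__(self) -> None:
        for name in ("rt_min_range", "ms1_mass_range", "ms2_mass_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered low <= high, got {lo}..{hi}")
        if self.min_peak_height < 0 or self.msms_abundance_cutoff < 0:
            raise ValueError("cutoffs must be >= 0")


@dataclass
class FilterCounts:
    """Per-rule drop counts emitted by :func:`filter_features`."""

    n_in: int = 0
    n_out: int = 0
    dropped_rt: int = 0
    dropped_mz: int = 0
    dropped_height: int = 0


def filter_features(table: FeatureTable, cfg: PreprocessConfig | None = None
                    ) -> tuple[FeatureTable, FilterCounts]:
    """Keep features inside the RT and MS1 mass ranges with sufficient height.

    A feature failing several rules is counted once, under the first failing
    rule in the order RT, m/z, height.
    """
    cfg = cfg or PreprocessConfig()
    counts = FilterCounts(n_in=len(table))
    kept = []
    rt_lo, rt_hi = cfg.rt_min_range
    mz_lo, mz_hi = cfg.ms1_mass_range
    for f in table:
        if not rt_lo <= f.rt_min <= rt_hi:
            counts.dropped_rt += 1
        elif not mz_lo <= f.precursor_mz <= mz_hi:
            counts.dropped_mz += 1
        elif f.height < cfg.min_peak_height:
            counts.dropped_height += 1
        else:
            kept.append(f)
    counts.n_out = len(kept)
    log.info("filter_features: %d -> %d (rt %d, mz %d, height %d dropped)",
             counts.n_in, counts.n_out, counts.dropped_rt, counts.dropped_mz,
             counts.dropped_height)
    return FeatureTable(kept, mode=table.mode), counts


def filter_spectrum_peaks(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Drop fragment peaks below the abundance cutoff or outside the MS2 range.

    The precursor is untouched. A spectrum losing every peak is returned
    empty and flagged in its metadata; networking excludes such spectra.
    """
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.ms2_mass_range
    kept = [p for p in s.peaks
            if p.intensity >= cfg.msms_abundance_cutoff and lo <= p.mz <= hi]
    out = s.replace_peaks(kept)
    if not kept:
        out.metadata["empty_after_filtering"] = True
    return out


def filter_spectra(spectra, cfg: PreprocessConfig | None = None) -> list[Spectrum]:
    """Apply :func:`filter_spectrum_peaks` to a collection."""
    cfg = cfg or PreprocessConfig()
    return [filter_spectrum_peaks(s, cfg) for s in spectra]
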