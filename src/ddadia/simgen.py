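"""Synthetic paired DDA/DIA datasets with planted ground truth.

The generator emulates the premise of a dual-acquisition untargeted LC-MS/MS
run over a plant extract: compound *families* share a fragment scaffold (so
intra-family modified-cosine similarity is high, as in a polyphenol cluster
with characteristic fragments), each member adds its own fragments, every
compound is seen in DIA, only a fraction is picked in DDA, and DIA spectra
are chimeric — contaminated by fragment peaks of co-eluting precursors.
Unrelated decoy features model background ions with no family structure.

DDA coverage is applied as an exact per-family fraction
(``round(members_per_family * dda_coverage)`` members drawn without
replacement) so every family's DDA presence matches the nominal rate; one
family can carry a fixed "anchor" scaffold (three diagnostic polyphenol
fragments at 300.9980, 255.0646 and 169.0130 Da) so the documented example
reproduces a recognisable polyphenol cluster.

All randomness flows from one seed; identical configurations produce
byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import Feature, FeatureTable, Mode, Peak, RetainedFeature, Spectrum
from . import spectra_io

#: diagnostic polyphenol fragment m/z values used for the anchor family
ANCHOR_SCAFFOLD = (300.9980, 255.0646, 169.0130)

#: co-elution window within which DIA spectra pick up foreign fragments
COELUTION_WINDOW_MIN = 0.1


@dataclass
class SimConfig:
    n_families: int = 10
    members_per_family: int = 8
    scaffold_peaks: int = 6          # shared fragments per family
    member_extra_peaks: int = 6      # member-specific fragments
    mz_jitter_sd: float = 0.003      # Da, per observed m/z
    rt_jitter_sd: float = 0.01       # min, per observed RT
    dda_coverage: float = 0.6        # fraction of family members with DDA MS2
    dia_contamination: float = 0.3   # fraction of DIA peaks injected from co-eluters
    decoy_features: int = 20         # unrelated background features (DIA only)
    intensity_log_sd: float = 0.5    # lognormal member-to-member spread
    seed: int = 42
    anchor_family: bool = True       # family 0 carries ANCHOR_SCAFFOLD fragments

    def __post_init__(self) -> None:
        if not (0 <= self.dda_coverage <= 1 and 0 <= self.dia_contamination <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        for name in ("n_families", "members_per_family", "scaffold_peaks",
                     "member_extra_peaks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mz_jitter_sd < 0 or self.rt_jitter_sd < 0 or self.intensity_log_sd < 0:
            raise ValueError("spread parameters must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    feature_id: str
    family_id: Optional[int]     # None for decoys
    compound_id: str
    mode: Mode
    counterpart_id: Optional[str]  # opposite-mode feature of the same compound


@dataclass
class GroundTruth:
    """Per-feature provenance of a simulated dataset."""

    records: dict[str, TruthRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def families_with_dda(self) -> set[int]:
        return {r.family_id for r in self.records.values()
                if r.family_id is not None and r.mode is Mode.DDA}

    def cross_mode_positive_ids(self) -> set[str]:
        """Features the cross-mode stage should recover.

        A feature is a planted positive when its family has at least one
        DDA-acquired member: every such feature sits in a component anchored
        in the DDA network, which is exactly the support the method detects.
        Decoys and members of DDA-free families are negatives.
        """
        eligible = self.families_with_dda()
        return {fid for fid, r in self.records.items()
                if r.family_id in eligible}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "feature_id": r.feature_id,
            "family_id": "" if r.family_id is None else r.family_id,
            "compound_id": r.compound_id,
            "mode": r.mode.value,
            "counterpart_id": r.counterpart_id or "",
        } for r in self.records.values()],
            columns=["feature_id", "family_id", "compound_id", "mode",
                     "counterpart_id"])

    def write(self, path) -> None:
        self.to_dataframe().to_csv(Path(path), sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GroundTruth":
        df = pd.read_csv(Path(path), sep="\t", dtype=str).fillna("")
        truth = cls()
        for row in df.itertuples(index=False):
            truth.records[row.feature_id] = TruthRecord(
                feature_id=row.feature_id,
                family_id=None if row.family_id == "" else int(float(row.family_id)),
                compound_id=row.compound_id,
                mode=Mode(row.mode),
                counterpart_id=row.counterpart_id or None)
        return truth


@dataclass
class SimulatedDataset:
    dda_spectra: list[Spectrum]
    dia_spectra: list[Spectrum]
    dda_table: FeatureTable
    dia_table: FeatureTable
    truth: GroundTruth

    def spectra_by_id(self) -> dict[str, Spectrum]:
        return {s.spectrum_id: s for s in self.dda_spectra + self.dia_spectra}


@dataclass
class _Compound:
    compound_id: str
    family_id: Optional[int]
    precursor_mz: float
    rt_min: float
    peaks: list[Peak]
    has_dda: bool


def simulate(cfg: SimConfig | None = None) -> SimulatedDataset:
    """Generate one paired DDA/DIA acquisition with planted ground truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    total = cfg.n_families * cfg.members_per_family + cfg.decoy_features
    if cfg.dia_contamination > 0 and total < 2:
        raise ValueError("contamination requires at least two features")

    compounds: list[_Compound] = []
    for f in range(cfg.n_families):
        scaffold_mz = np.sort(rng.uniform(100.0, 450.0, cfg.scaffold_peaks))
        if f == 0 and cfg.anchor_family:
            k = min(len(ANCHOR_SCAFFOLD), cfg.scaffold_peaks)
            scaffold_mz[:k] = ANCHOR_SCAFFOLD[:k]
            scaffold_mz = np.sort(scaffold_mz)
        # diagnostic scaffold fragments dominate the spectrum, as the
        # characteristic fragments of a compound class do in real MS2; the
        # ~25x median ratio over member-specific peaks keeps intra-family
        # modified cosine high while member peaks stay well above typical
        # abundance cutoffs
        scaffold_base = rng.lognormal(math.log(20000.0), 0.4, cfg.scaffold_peaks)

        n_dda = int(round(cfg.members_per_family * cfg.dda_coverage))
        dda_members = set(rng.choice(cfg.members_per_family, size=n_dda,
                                     replace=False)) if n_dda else set()
        for m in range(cfg.members_per_family):
            precursor = float(rng.uniform(455.0, 1000.0))
            rt = float(rng.uniform(0.6, 34.9))
            scaffold_int = scaffold_base * rng.lognormal(
                0.0, cfg.intensity_log_sd, cfg.scaffold_peaks)
            extra_mz = rng.uniform(100.0, precursor - 5.0, cfg.member_extra_peaks)
            extra_int = rng.lognormal(math.log(800.0), cfg.intensity_log_sd,
                                      cfg.member_extra_peaks)
            peaks = [Peak(float(mz), float(i)) for mz, i in
                     zip(scaffold_mz, scaffold_int)]
            peaks += [Peak(float(mz), float(i)) for mz, i in
                      zip(extra_mz, extra_int)]
            compounds.append(_Compound(
                compound_id=f"F{f}M{m}", family_id=f, precursor_mz=precursor,
                rt_min=rt, peaks=peaks, has_dda=m in dda_members))

    for d in range(cfg.decoy_features):
        precursor = float(rng.uniform(150.0, 1000.0))
        n_peaks = cfg.scaffold_peaks + cfg.member_extra_peaks
        mz = rng.uniform(100.0, precursor - 5.0, n_peaks)
        inten = rng.lognormal(math.log(1500.0), 0.7, n_peaks)
        compounds.append(_Compound(
            compound_id=f"X{d}", family_id=None,
            precursor_mz=precursor, rt_min=float(rng.uniform(0.6, 34.9)),
            peaks=[Peak(float(a), float(b)) for a, b in zip(mz, inten)],
            has_dda=False))

    def observe(c: _Compound, peaks: Sequence[Peak]) -> tuple[float, float, list[Peak]]:
        mz_obs = float(c.precursor_mz + rng.normal(0.0, cfg.mz_jitter_sd))
        rt_obs = float(max(0.0, c.rt_min + rng.normal(0.0, cfg.rt_jitter_sd)))
        obs = [Peak(float(p.mz + rng.normal(0.0, cfg.mz_jitter_sd)),
                    float(p.intensity * rng.lognormal(0.0, 0.2)))
               for p in peaks]
        return mz_obs, rt_obs, obs

    dia_spectra: list[Spectrum] = []
    dia_features: list[Feature] = []
    dda_spectra: list[Spectrum] = []
    dda_features: list[Feature] = []
    truth = GroundTruth()

    for c in compounds:
        # chimeric DIA measurement: own peaks plus scaled fragments of
        # co-eluting compounds (additive, never replacing true peaks)
        peaks = list(c.peaks)
        if cfg.dia_contamination > 0:
            neighbours = [o for o in compounds if o.compound_id != c.compound_id
                          and abs(o.rt_min - c.rt_min) <= COELUTION_WINDOW_MIN]
            pool = [p for o in neighbours for p in o.peaks]
            n_inject = int(round(cfg.dia_contamination * len(c.peaks)))
            if pool and n_inject:
                idx = rng.choice(len(pool), size=min(n_inject, len(pool)),
                                 replace=False)
                for i in sorted(idx):
                    p = pool[i]
                    peaks.append(Peak(p.mz, p.intensity *
                                      float(rng.uniform(0.2, 0.8))))
        dia_id = f"DIA_{c.compound_id}"
        mz_obs, rt_obs, obs = observe(c, peaks)
        dia_spectra.append(Spectrum(dia_id, mz_obs, rt_obs, obs, mode=Mode.DIA))
        dia_features.append(Feature(
            dia_id, mz_obs, rt_obs,
            height=float(2500.0 + rng.lognormal(math.log(5e4), 0.8)),
            spectrum_ref=dia_id, mode=Mode.DIA))

        dda_id = f"DDA_{c.compound_id}" if c.has_dda else None
        if c.has_dda:
            mz_d, rt_d, obs_d = observe(c, c.peaks)  # clean DDA spectrum
            dda_spectra.append(Spectrum(dda_id, mz_d, rt_d, obs_d, mode=Mode.DDA))
            dda_features.append(Feature(
                dda_id, mz_d, rt_d,
                height=float(2500.0 + rng.lognormal(math.log(5e4), 0.8)),
                spectrum_ref=dda_id, mode=Mode.DDA))
            truth.records[dda_id] = TruthRecord(dda_id, c.family_id,
                                                c.compound_id, Mode.DDA, dia_id)
        truth.records[dia_id] = TruthRecord(dia_id, c.family_id, c.compound_id,
                                            Mode.DIA, dda_id)

    return SimulatedDataset(
        dda_spectra=dda_spectra, dia_spectra=dia_spectra,
        dda_table=FeatureTable(dda_features, mode=Mode.DDA),
        dia_table=FeatureTable(dia_features, mode=Mode.DIA),
        truth=truth)


def simulate_to_dir(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Run :func:`simulate` and write MGF/TSV artefacts to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate(cfg)
    paths = {
        "dda_mgf": outdir / "dda.mgf",
        "dia_mgf": outdir / "dia.mgf",
        "dda_table": outdir / "dda_features.tsv",
        "dia_table": outdir / "dia_features.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    spectra_io.write_mgf(ds.dda_spectra, paths["dda_mgf"])
    spectra_io.write_mgf(ds.dia_spectra, paths["dia_mgf"])
    spectra_io.write_feature_table(ds.dda_table, paths["dda_table"])
    spectra_io.write_feature_table(ds.dia_table, paths["dia_table"])
    ds.truth.write(paths["ground_truth"])
    return paths


@dataclass
class EvaluationMetrics:
    precision: Optional[float]
    recall: Optional[float]
    component_purity: Optional[float]
    n_retained: int
    n_positive: int
    n_true_retained: int


def evaluate(retained: Sequence[RetainedFeature], truth: GroundTruth
             ) -> EvaluationMetrics:
    """Precision/recall of the retained set against the planted positives.

    Purity averages, over components with retained members, the largest
    single-family share among them (decoys count as one pseudo-family).
    """
    ids = {r.feature_id for r in retained}
    orphans = sorted(i for i in ids if i not in truth.records)
    if orphans:
        raise ValueError(f"retained features unknown to ground truth: {orphans}")
    positives = truth.cross_mode_positive_ids()
    tp = len(ids & positives)
    precision = tp / len(ids) if ids else None
    recall = tp / len(positives) if positives else None

    by_component: dict[int, list[str]] = {}
    for r in retained:
        by_component.setdefault(r.component_id, []).append(r.feature_id)
    purities = []
    for members in by_component.values():
        labels = ["decoy" if truth.records[m].family_id is None
                  else f"fam{truth.records[m].family_id}" for m in members]
        top = max(labels.count(l) for l in set(labels))
        purities.append(top / len(members))
    purity = float(np.mean(purities)) if purities else None
    return EvaluationMetrics(precision=precision, recall=recall,
                             component_purity=purity, n_retained=len(ids),
                             n_positive=len(positives), n_true_retained=tp)


def clean_config(cfg: SimConfig | None = None) -> SimConfig:
    """The contamination-free, decoy-free variant of a configuration."""
    return replace(cfg or SimConfig(), dia_contamination=0.0, decoy_features=0)
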