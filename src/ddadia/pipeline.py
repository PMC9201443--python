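"""End-to-end orchestration and the run manifest.

``run_all`` executes preprocess -> DDA network -> component selection ->
merge -> cross network -> retention -> annotation on in-memory inputs and
returns every intermediate product plus a manifest of per-stage counts;
``run_all_files`` is the file-based variant the CLI wraps, writing all
artefacts and a JSON manifest whose digests make a run reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from . import __version__, spectra_io
from .annotation import AnnotationResult, annotate
from .config import RunConfig
from .crossmode import run_crossmode
from .models import FeatureTable, Mode, MolecularNetwork, RetainedFeature, Spectrum
from .preprocess import filter_features, filter_spectra

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    tool_version: str
    seed: Optional[int]
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


@dataclass
class PipelineResult:
    dda_network: MolecularNetwork
    selected_ids: set[str]
    merged_table: FeatureTable
    cross_network: MolecularNetwork
    retained: list[RetainedFeature]
    annotation: Optional[AnnotationResult]
    manifest: RunManifest


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(dda_spectra: Mapping[str, Spectrum], dda_table: FeatureTable,
            dia_spectra: Mapping[str, Spectrum], dia_table: FeatureTable,
            cfg: RunConfig | None = None,
            library=None, seed: Optional[int] = None) -> PipelineResult:
    """Run the full DDA-assisted DIA chain on in-memory inputs."""
    cfg = cfg or RunConfig()
    counts: dict[str, int] = {}

    dda_filt, c_dda = filter_features(dda_table, cfg.preprocess)
    dia_filt, c_dia = filter_features(dia_table, cfg.preprocess)
    counts["dda_features_in"] = c_dda.n_in
    counts["dda_features_kept"] = c_dda.n_out
    counts["dia_features_in"] = c_dia.n_in
    counts["dia_features_kept"] = c_dia.n_out

    dda_sp = {s.spectrum_id: s for s in
              filter_spectra(dda_spectra.values(), cfg.preprocess)}
    dia_sp = {s.spectrum_id: s for s in
              filter_spectra(dia_spectra.values(), cfg.preprocess)}

    dda_net, selected, merged, cross, retained = run_crossmode(
        dda_sp, dda_filt, dia_sp, dia_filt,
        net_cfg=cfg.networking, score_cfg=cfg.similarity, cfg=cfg.crossmode)
    counts["dda_network_nodes"] = dda_net.n_nodes()
    counts["dda_network_edges"] = dda_net.n_edges()
    counts["dda_network_components"] = len(dda_net.components)
    counts["dda_selected_features"] = len(selected)
    counts["merged_features"] = len(merged.table)
    counts["cross_network_nodes"] = cross.n_nodes()
    counts["cross_network_edges"] = cross.n_edges()
    counts["retained_features"] = len(retained)
    counts["retained_dda"] = sum(1 for r in retained if r.provenance is Mode.DDA)
    counts["retained_dia"] = sum(1 for r in retained if r.provenance is Mode.DIA)

    ann = None
    if library:
        merged_by_id = merged.table.by_id()
        all_sp = dict(dia_sp)
        all_sp.update(dda_sp)
        feats = [merged_by_id[r.feature_id] for r in retained]
        ann = annotate(feats, all_sp, library, cfg.annotation)
        counts["annotation_hits"] = len(ann.hits)
        counts["annotated_features"] = len({h.feature_id for h in ann.hits})
        counts["unannotated_features"] = len(ann.unannotated)

    manifest = RunManifest(tool_version=__version__, seed=seed,
                           config=cfg.to_dict(), stage_counts=counts)
    return PipelineResult(dda_network=dda_net, selected_ids=selected,
                          merged_table=merged.table, cross_network=cross,
                          retained=retained, annotation=ann, manifest=manifest)


def run_all_files(dda_mgf, dda_table_path, dia_mgf, dia_table_path,
                  outdir, cfg: RunConfig | None = None, library_path=None,
                  seed: Optional[int] = None) -> PipelineResult:
    """File-based pipeline: read inputs, run, write artefacts + manifest."""
    cfg = cfg or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    dda_spectra = {s.spectrum_id: s for s in
                   spectra_io.read_mgf(dda_mgf, mode=Mode.DDA)}
    dia_spectra = {s.spectrum_id: s for s in
                   spectra_io.read_mgf(dia_mgf, mode=Mode.DIA)}
    dda_table, rej_a = spectra_io.read_feature_table(dda_table_path, Mode.DDA)
    dia_table, rej_b = spectra_io.read_feature_table(dia_table_path, Mode.DIA)
    for rep, name in ((rej_a, "DDA"), (rej_b, "DIA")):
        if len(rep):
            log.warning("%s feature table: %d rejected rows", name, len(rep))
    library = spectra_io.read_msp(library_path) if library_path else None

    result = run_all(dda_spectra, dda_table, dia_spectra, dia_table,
                     cfg=cfg, library=library, seed=seed)

    spectra_io.write_network(result.dda_network, outdir / "dda_network.graphml")
    spectra_io.write_network(result.cross_network, outdir / "cross_network.graphml")
    spectra_io.write_network(result.cross_network, outdir / "cross_network",
                             format="edge_tsv")
    spectra_io.write_feature_table(result.merged_table, outdir / "merged_features.tsv")
    _write_retained(result.retained, outdir / "retained_features.tsv")
    if result.annotation is not None:
        result.annotation.to_dataframe().to_csv(
            outdir / "annotation_hits.tsv", sep="\t", index=False)

    for key, p in (("dda_mgf", dda_mgf), ("dia_mgf", dia_mgf),
                   ("dda_table", dda_table_path), ("dia_table", dia_table_path)):
        result.manifest.input_digests[key] = sha256_file(p)
    if library_path:
        result.manifest.input_digests["library"] = sha256_file(library_path)
    result.manifest.write(outdir / "manifest.json")
    return result


def _write_retained(retained, path) -> None:
    import pandas as pd
    pd.DataFrame([{
        "feature_id": r.feature_id,
        "provenance": r.provenance.value,
        "component_id": r.component_id,
        "linked_ids": ";".join(sorted(r.linked_ids)),
    } for r in retained],
        columns=["feature_id", "provenance", "component_id", "linked_ids"]
    ).to_csv(Path(path), sep="\t", index=False)
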