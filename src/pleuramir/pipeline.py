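"""End-to-end pipeline driver: QC -> normalization -> DE -> marker ranking.

Every stage writes its table under the run directory; a JSON run manifest
records the configuration snapshot, input digests, per-stage counts and the
package version, so a run can be reproduced bit-for-bit from the manifest
alone (output tables are deterministic given config + inputs; the manifest's
timestamp is informational).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import classifier_eval as ce
from . import diffexpr as de
from . import io_qpcr, preprocess

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "run_pipeline"]

log = logging.getLogger("pleuramir")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters with their documented defaults.

    Defaults encode the analysis conditions the pipeline targets: sample QC
    threshold 0.80, reference eligibility of at most 3 undetected samples,
    4 reference probes, candidate gate adj_p < 0.05 and |logFC| > 3, and
    500 stratified 2:1 split repeats.
    """

    sample_threshold: float = 0.80
    n_refs: int = 4
    max_undetected: int = 3
    p_cut: float = 0.05
    lfc_cut: float = 3.0
    n_repeats: int = 500
    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    outdir: Path | None = None


@dataclass
class RunManifest:
    config: dict
    version: str
    input_digests: dict[str, str]
    stage_counts: dict[str, int] = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   default=str) + "\n")


@dataclass
class PipelineResult:
    ct_filtered: pd.DataFrame
    dct: pd.DataFrame
    references: preprocess.ReferenceSet
    qc_probes: preprocess.QcReport
    qc_samples: preprocess.QcReport
    de_table: pd.DataFrame
    moderation: de.ModerationFit
    candidates: pd.DataFrame
    evaluations: list[ce.MarkerEvaluation]
    manifest: RunManifest


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv().encode("utf-8")).hexdigest()[:16]


def run_pipeline(ct: pd.DataFrame, sheet: pd.DataFrame,
                 config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Execute all stages in order on an in-memory Ct matrix + sample sheet.

    Stage order: filter_probes -> filter_samples -> select_references ->
    delta_normalize -> differential expression -> per-candidate classifier
    evaluation -> ranking. If ``config.outdir`` is set, every stage table
    and the manifest are persisted there.
    """
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        input_digests={"ct_matrix": _digest(ct), "sample_sheet": _digest(sheet)},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    groups = sheet.set_index("sample_id")["group"]

    ct1, qc_probes = preprocess.filter_probes(ct)
    log.info("probe QC: %d -> %d probes", qc_probes.n_probes_in,
             qc_probes.n_probes_kept)
    ct2, qc_samples = preprocess.filter_samples(
        ct1, threshold=config.sample_threshold, groups=groups)
    log.info("sample QC: %d -> %d samples", qc_samples.n_samples_in,
             qc_samples.n_samples_kept)
    refs = preprocess.select_references(
        ct2, k=config.n_refs, max_undetected=config.max_undetected)
    log.info("reference probes: %s", ", ".join(refs.probe_ids))
    dct = preprocess.delta_normalize(ct2, refs)

    design = de.GroupDesign.from_sample_sheet(sheet, sample_ids=ct2.columns)
    de_table, fit = de.run_diffexpr(dct, design, p_cut=config.p_cut,
                                    lfc_cut=config.lfc_cut)
    candidates = de_table.loc[de_table["candidate"]].reset_index(drop=True)

    y = np.asarray(dct.columns.map(groups) == "cancer", dtype=int)
    evaluations: list[ce.MarkerEvaluation] = []
    for probe in candidates["probe_id"]:
        x = -dct.loc[probe].to_numpy()   # expression proxy, higher = more abundant
        evaluations.append(ce.evaluate_marker(
            probe, x, y, n_repeats=config.n_repeats, seed=config.seed))
    if evaluations:
        evaluations = ce.rank_markers(evaluations)
    else:
        log.info("no candidates passed the gate; marker report is empty")

    manifest.stage_counts = {
        "probes_in": qc_probes.n_probes_in,
        "probes_removed_all40": qc_probes.n_probes_removed_all40,
        "probes_kept": qc_probes.n_probes_kept,
        "samples_in": qc_samples.n_samples_in,
        "samples_removed": qc_samples.n_samples_removed,
        "samples_kept": qc_samples.n_samples_kept,
        "n_candidates": len(candidates),
        "n_control": design.n1,
        "n_cancer": design.n2,
    }

    result = PipelineResult(
        ct_filtered=ct2, dct=dct, references=refs, qc_probes=qc_probes,
        qc_samples=qc_samples, de_table=de_table, moderation=fit,
        candidates=candidates, evaluations=evaluations, manifest=manifest)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_qpcr.write_ct_matrix(ct2, outdir / "ct_filtered.csv")
        io_qpcr.write_ct_matrix(dct, outdir / "delta_ct.csv")
        io_qpcr.write_de_results(de_table, outdir / "diffexpr.csv")
        report = ce.evaluations_to_frame(evaluations) if evaluations \
            else pd.DataFrame(columns=["probe"])
        io_qpcr.write_marker_evaluations(report, outdir / "markers.csv")
        pd.DataFrame({"reference_probe": list(refs.probe_ids),
                      "iqr": [refs.iqr[p] for p in refs.probe_ids]}
                     ).to_csv(outdir / "references.csv", index=False)
        manifest.write(outdir / "manifest.json")
    return result
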