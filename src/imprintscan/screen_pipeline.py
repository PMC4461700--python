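"""End-to-end screen: load -> quantify -> classify -> reconcile -> report.

The screen is evaluated blind: methylation and dosage calls are computed from
the peak data alone, and trio segregation results (when a trio file is given)
are reconciled into the mechanism hypotheses only afterwards, so the presence
of trio data never changes a methylation or dosage class.  Reports are
deterministic: identical inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import quantify as _quantify
from .classify import EpigenotypeCall, NormalRange, SampleSummary, _chrom_of
from .errors import ValidationError
from .panel_io import (
    PanelConfig,
    Role,
    SamplePair,
    read_panel_config,
    read_peak_table,
    read_trio_genotypes,
    pair_runs,
)
from .quantify import ControlBaseline, DenominatorMode, LocusMeasurement
from .upd_trio import UPDCall, analyze_trios

SCHEMA_VERSION = 1

try:
    __version__ = metadata.version("imprintscan")
except metadata.PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


@dataclass(frozen=True)
class SampleBlock:
    sample_id: str
    measurements: tuple[LocusMeasurement, ...]
    calls: tuple[EpigenotypeCall, ...]
    summary: SampleSummary
    upd_calls: tuple[UPDCall, ...] = ()


@dataclass(frozen=True)
class ScreenReport:
    """Everything the screen produced, plus provenance for reruns."""

    panel_name: str
    panel_version: str
    denominator_mode: DenominatorMode
    normal_range: NormalRange
    samples: tuple[SampleBlock, ...]
    cohort_summary: dict
    control_qc: tuple[dict, ...] = ()
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def scrub(obj):
            if isinstance(obj, dict):
                return {k: scrub(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [scrub(v) for v in obj]
            if isinstance(obj, frozenset):
                return sorted(obj)
            return obj

        return {
            "schema_version": SCHEMA_VERSION,
            "panel": {"name": self.panel_name, "version": self.panel_version},
            "parameters": {
                "denominator_mode": self.denominator_mode.value,
                "normal_range": asdict(self.normal_range),
            },
            "cohort_summary": scrub(self.cohort_summary),
            "control_qc": scrub(list(self.control_qc)),
            "samples": [scrub(asdict(block)) for block in self.samples],
            "provenance": scrub(self.provenance),
        }


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_screen(
    peaks: str | Path,
    panel: str | Path | PanelConfig,
    controls: list[str] | None = None,
    trios: str | Path | None = None,
    mode: DenominatorMode | str = DenominatorMode.REFERENCE_ONLY,
    normal_range: NormalRange = NormalRange(),
    min_controls: int = _quantify.DEFAULT_MIN_CONTROLS,
    allow_low_controls: bool = False,
    min_supporting_markers: int = 3,
    out_dir: str | Path | None = None,
) -> ScreenReport:
    """Run the whole screen on a peak table and write the report files.

    Controls are designated explicitly (``controls`` id list or a ``role``
    column in the peak CSV) — never inferred from looking normal, which would
    bias the baseline.  Patients are quantified against the control baseline,
    classified, and (optionally) reconciled with trio UPD verdicts matched by
    ``trio_id == sample_id`` and chromosome.
    """
    mode = DenominatorMode(mode)
    provenance: dict = {"tool_version": __version__,
                        "denominator_mode": mode.value}

    if isinstance(panel, PanelConfig):
        panel_cfg = panel
    else:
        panel_cfg = read_panel_config(panel)
        provenance["panel_file"] = {"path": str(panel),
                                    "sha256": _sha256(panel)}
    records = read_peak_table(peaks, panel_cfg)
    provenance["peaks_file"] = {"path": str(peaks), "sha256": _sha256(peaks)}

    pairs = pair_runs(records, panel_cfg, controls=controls)
    control_pairs = [p for p in pairs if p.role is Role.CONTROL]
    patient_pairs = [p for p in pairs if p.role is not Role.CONTROL]
    if not control_pairs:
        raise ValidationError(
            "no control samples designated (pass a controls list or add a "
            "role column to the peak table)")

    baseline = _quantify.build_baseline(
        control_pairs, panel_cfg, mode,
        min_controls=min_controls, allow_low_n=allow_low_controls)
    control_qc = _quantify.control_leave_one_out(
        control_pairs, panel_cfg, mode,
        low=normal_range.low, high=normal_range.high)

    upd_by_key: dict[tuple[str, str], UPDCall] = {}
    if trios is not None:
        genotypes = read_trio_genotypes(trios)
        provenance["trios_file"] = {"path": str(trios),
                                    "sha256": _sha256(trios)}
        for call in analyze_trios(genotypes,
                                  min_supporting=min_supporting_markers):
            upd_by_key[(call.trio_id, _chrom_of(call.chrom))] = call

    blocks: list[SampleBlock] = []
    n_positive = 0
    n_multilocus = 0
    for pair in sorted(patient_pairs, key=lambda p: p.sample_id):
        measurements = _quantify.measure_loci(pair, baseline, panel_cfg)
        calls, summary = _classify.screen_sample(
            measurements, panel_cfg, normal_range)
        sample_upds = []
        reconciled = []
        for call in calls:
            upd = upd_by_key.get((pair.sample_id, _chrom_of(call.chrom_band)))
            if upd is not None and upd not in sample_upds:
                sample_upds.append(upd)
            reconciled.append(_classify.reconcile_with_upd(call, upd))
        n_positive += summary.positive
        n_multilocus += summary.multilocus_candidate
        blocks.append(SampleBlock(
            sample_id=pair.sample_id,
            measurements=tuple(measurements),
            calls=tuple(reconciled),
            summary=summary,
            upd_calls=tuple(sample_upds),
        ))

    report = ScreenReport(
        panel_name=panel_cfg.name,
        panel_version=panel_cfg.version,
        denominator_mode=mode,
        normal_range=normal_range,
        samples=tuple(blocks),
        cohort_summary={
            "n_screened": len(blocks),
            "n_controls": len(control_pairs),
            "n_positive": n_positive,
            "n_multilocus_candidates": n_multilocus,
            "positive_samples": sorted(
                b.sample_id for b in blocks if b.summary.positive),
        },
        control_qc=tuple(control_qc),
        provenance=provenance,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: ScreenReport, out_dir: str | Path) -> dict[str, Path]:
    """Write report.json, calls.tsv and measurements.tsv.

    Output is stable: keys sorted, floats via repr, no timestamps, so
    re-running on identical inputs is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    json_path = out_dir / "report.json"
    json_path.write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8")

    meas_rows = [{
        "sample_id": m.sample_id,
        "locus": m.locus,
        "M": m.M,
        "D": m.D,
        "M_per_copy": m.M_per_copy,
        "percent_loss": m.percent_loss,
        "percent_gain": m.percent_gain,
        "flags": ";".join(sorted(m.flags)),
    } for block in report.samples for m in block.measurements]
    meas_path = out_dir / "measurements.tsv"
    pd.DataFrame(meas_rows, columns=[
        "sample_id", "locus", "M", "D", "M_per_copy", "percent_loss",
        "percent_gain", "flags"]).to_csv(meas_path, sep="\t", index=False)

    call_rows = [{
        "sample_id": c.sample_id,
        "locus": c.locus,
        "M": c.M,
        "D": c.D,
        "methylation_class": c.methylation_class.value,
        "dosage_class": c.dosage_class.value,
        "mechanisms": ";".join(h.mechanism.value for h in c.mechanisms),
        "confirmed_mechanism": c.confirmed_mechanism,
        "recommendation": c.recommendation,
        "multilocus_candidate": c.multilocus_candidate,
    } for block in report.samples for c in block.calls]
    calls_path = out_dir / "calls.tsv"
    pd.DataFrame(call_rows, columns=[
        "sample_id", "locus", "M", "D", "methylation_class", "dosage_class",
        "mechanisms", "confirmed_mechanism", "recommendation",
        "multilocus_candidate"]).to_csv(calls_path, sep="\t", index=False)

    return {"report": json_path, "measurements": meas_path,
            "calls": calls_path}


def read_report(path: str | Path) -> dict:
    """Load a report.json back into its dictionary form."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
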