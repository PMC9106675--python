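"""End-to-end orchestration: prep -> superpose -> descriptors -> Dscore ->
classification -> aggregation -> reports.

The run is manifest-driven: a TSV lists every structure with its target,
crystal form, seeding-ligand residue name and (for apo and protein/peptide
bound forms) the ligand-bound reference entry whose posed inhibitor
identifies the pocket.  Failures are isolated per structure -- a malformed
entry is logged and skipped, never fatal for the batch -- and re-running
with the same config is bit-identical (nothing in the pipeline is random).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import druggability, structure_io, superpose
from .druggability import DruggabilityRecord, TargetSummary
from .pocket_descriptors import PocketConfig, detect_site
from .structure_io import LigandMolecule, ProteinStructure

logger = logging.getLogger("ppidrugg")

__all__ = ["RunConfig", "RunReport", "run", "render_tables", "process_structure"]

MANIFEST_COLUMNS = ("structure_id", "pdb_path", "target", "form", "ligand", "reference_id")


@dataclass
class RunConfig:
    manifest: pd.DataFrame
    base_dir: Path = Path(".")
    pocket: PocketConfig = field(default_factory=PocketConfig)
    scheme: str = "ppi4"  # or "halgren3"
    output_dir: Path = Path("ppidrugg_out")
    activities: dict[str, float] | None = None  # structure_id -> IC50 (nM)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        manifest = pd.read_csv(base / raw["manifest"], sep="\t", dtype=str)
        missing = [c for c in MANIFEST_COLUMNS[:5] if c not in manifest.columns]
        if missing:
            raise ValueError(f"manifest lacks required columns: {missing}")
        if "reference_id" not in manifest.columns:
            manifest["reference_id"] = None
        pocket = PocketConfig(**(raw.get("pocket") or {}))
        activities = None
        if raw.get("activities"):
            act = pd.read_csv(base / raw["activities"], sep="\t")
            activities = dict(zip(act["structure_id"].astype(str), act["ic50_nm"].astype(float)))
        return cls(
            manifest=manifest,
            base_dir=base,
            pocket=pocket,
            scheme=raw.get("scheme", "ppi4"),
            output_dir=base / raw.get("output_dir", "ppidrugg_out"),
            activities=activities,
        )

    def __post_init__(self) -> None:
        if self.scheme not in ("ppi4", "halgren3"):
            raise ValueError(f"unknown classification scheme {self.scheme!r}")
        refs_needed = self.manifest[
            self.manifest["form"].isin(["apo", "protein_peptide_bound"])
        ]
        ids = set(self.manifest["structure_id"])
        for _, row in refs_needed.iterrows():
            ref = row.get("reference_id")
            if not ref or pd.isna(ref) or ref not in ids:
                raise ValueError(
                    f"{row['structure_id']}: apo/protein-bound entries must name "
                    "a ligand-bound reference present in the manifest"
                )


@dataclass
class RunReport:
    records: list[DruggabilityRecord]
    summaries: dict[str, TargetSummary]
    correlations: list[druggability.CorrelationResult]
    skipped: list[tuple[str, str]]  # (structure_id, reason)
    log: list[str]

    def records_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = r.descriptors
            rows.append(
                {
                    "structure_id": r.structure_id,
                    "target": r.target,
                    "form": r.form,
                    "detected": d.detected,
                    "n": d.n if d.detected else None,
                    "e": round(d.e, 2) if d.detected else None,
                    "p": round(d.p, 2) if d.detected else None,
                    "dscore": round(r.dscore, 2) if r.dscore is not None else None,
                    "ppi_class": r.ppi_class,
                }
            )
        return pd.DataFrame(rows)


def _prepare(path: Path, ligand_name: str | None) -> tuple[ProteinStructure, LigandMolecule | None]:
    st = structure_io.read_pdb(path)
    ligand = None
    if ligand_name:
        stripped = structure_io.strip_non_protein(st, keep_ligand=ligand_name)
        try:
            ligand = structure_io.extract_ligand(stripped, ligand_name)
        except structure_io.AmbiguousLigandError:
            # keep the copy in the bound chain by trying chains in label order
            for cid in sorted(stripped.chains):
                try:
                    ligand = structure_io.extract_ligand(stripped, ligand_name, chain_id=cid)
                    break
                except structure_io.StructureError:
                    continue
            if ligand is None:
                raise
        st = structure_io.select_chain(stripped, ligand)
        st = structure_io.strip_non_protein(st)  # drop the ligand back out
    else:
        st = structure_io.strip_non_protein(st)
        if len(st.chains) > 1:
            raise structure_io.StructureError(
                f"{path.name}: apo/protein-bound entry has several chains; "
                "curate to the interface chain first"
            )
    return st, ligand


def process_structure(
    row: dict,
    base_dir: Path,
    pocket: PocketConfig,
    references: dict[str, tuple[ProteinStructure, LigandMolecule]],
) -> DruggabilityRecord:
    """Run one manifest entry through prep, (superposition,) and detection."""
    form = row["form"]
    path = base_dir / row["pdb_path"]
    if form == "ligand_bound":
        st, ligand = _prepare(path, row["ligand"])
    else:
        st, _ = _prepare(path, None)
        ref_st, ref_lig = references[row["reference_id"]]
        st, ligand, _fit = superpose.superpose_on_reference(st, ref_st, ref_lig)
    desc = detect_site(st, ligand, pocket)
    return druggability.make_record(row["structure_id"], row["target"], form, desc)


def run(config: RunConfig) -> RunReport:
    """Execute the full workflow for every manifest entry."""
    log: list[str] = []
    skipped: list[tuple[str, str]] = []
    records: list[DruggabilityRecord] = []

    # pass 1: prepare all ligand-bound references
    references: dict[str, tuple[ProteinStructure, LigandMolecule]] = {}
    ref_ids = set(config.manifest["reference_id"].dropna()) & set(
        config.manifest["structure_id"]
    )
    for _, row in config.manifest.iterrows():
        if row["structure_id"] in ref_ids and row["form"] == "ligand_bound":
            try:
                references[row["structure_id"]] = _prepare(
                    config.base_dir / row["pdb_path"], row["ligand"]
                )
            except Exception as exc:
                log.append(f"{row['structure_id']}: reference preparation failed: {exc}")

    for _, row in config.manifest.iterrows():
        sid = row["structure_id"]
        try:
            rec = process_structure(dict(row), config.base_dir, config.pocket, references)
            records.append(rec)
            outcome = (
                f"dscore={rec.dscore:.2f} class={rec.ppi_class}"
                if rec.dscore is not None
                else "ND (no site detected), class=difficult"
            )
            log.append(f"{sid}: {outcome}")
        except Exception as exc:
            skipped.append((sid, str(exc)))
            log.append(f"{sid}: SKIPPED ({exc})")
            logger.warning("skipping %s: %s", sid, exc)

    activities_pic50 = None
    if config.activities:
        activities_pic50 = {
            k: druggability.pic50(v * 1e-9) for k, v in config.activities.items()
        }
    summaries = {}
    for target in sorted({r.target for r in records}):
        summaries[target] = druggability.aggregate_target(
            [r for r in records if r.target == target], activities_pic50
        )

    correlations = []
    if len(summaries) >= 3:
        meds = [
            (s.overall["dscore"].median, s.overall["n"].median,
             s.overall["e"].median, s.overall["p"].median)
            for s in summaries.values()
        ]
        d, n, e, p = zip(*meds)
        for name, series in (("n", n), ("e", e), ("p", p)):
            try:
                correlations.append(
                    druggability.pearson_r2(
                        series, d, x_name=name, y_name="dscore", impute_nd_zero=True
                    )
                )
            except druggability.UndefinedCorrelationError:
                pass

    return RunReport(
        records=records,
        summaries=summaries,
        correlations=correlations,
        skipped=skipped,
        log=log,
    )


def _fmt(value, digits=2):
    if value is None:
        return "ND"
    return f"{value:.{digits}f}"


def summary_row(s: TargetSummary) -> dict:
    """One survey-style row: median with '(min-max)' range per metric."""
    row = {"target": s.target, "count": s.n_records}
    for metric, digits in (("dscore", 2), ("n", 0), ("e", 2), ("p", 2)):
        st = s.overall[metric]
        if st.count == 0:
            row[metric] = "ND"
        else:
            med = f"{st.median:.{digits}f}"
            row[metric] = f"{med} ({st.min:.{digits}f}–{st.max:.{digits}f})"
    row["ppi_class"] = s.ppi_class
    return row


def render_tables(report: RunReport, output_dir: str | Path) -> dict[str, Path]:
    """Write the report as TSV/JSON files; returns the paths written."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rec = report.records_frame()
    paths["records"] = out / "records.tsv"
    rec.to_csv(paths["records"], sep="\t", index=False)

    rows = [summary_row(s) for s in report.summaries.values()]
    paths["target_summary"] = out / "target_summary.tsv"
    pd.DataFrame(rows).to_csv(paths["target_summary"], sep="\t", index=False)

    classification = {
        t: {"median_dscore": s.median_dscore, "class": s.ppi_class}
        for t, s in report.summaries.items()
    }
    paths["classification"] = out / "classification.json"
    paths["classification"].write_text(json.dumps(classification, indent=2))

    if report.correlations:
        paths["correlations"] = out / "correlations.tsv"
        pd.DataFrame(
            [
                {"x": c.x_name, "y": c.y_name, "r": c.r, "r2": c.r2, "n": c.n_points}
                for c in report.correlations
            ]
        ).to_csv(paths["correlations"], sep="\t", index=False)

    scatter = [
        {"target": t, "mean_dscore": s.overall["dscore"].median or 0.0, "mean_pic50": s.mean_pic50}
        for t, s in report.summaries.items()
        if s.mean_pic50 is not None
    ]
    if scatter:
        paths["scatter"] = out / "scatter_pic50_dscore.csv"
        pd.DataFrame(scatter).to_csv(paths["scatter"], index=False)

    paths["log"] = out / "run.log"
    paths["log"].write_text("\n".join(report.log) + "\n")
    return paths
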