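"""Readers/writers for campaign tables, trees, reports, and overlay exports.

CSV dialect is fixed: UTF-8, comma separator, "." decimal mark, mandatory
header.  The JSON tree schema ("tba-tree v1") carries explicit units on
every quantity — this method is unit-bug-prone, so bare numbers are never
serialized.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from biopotency.errors import DomainError, SchemaError, TreeStructureError, UnitError
from biopotency.ledger import (
    CampaignReport,
    MaterialNode,
    MaterialRole,
    PurificationTree,
)
from biopotency.potency import Censoring, PotencyEstimate, parse_concentration

__all__ = [
    "CAMPAIGN_COLUMNS",
    "OverlayRecord",
    "read_campaign_csv",
    "write_campaign_csv",
    "read_tree_json",
    "write_tree_json",
    "write_report",
    "render_report",
    "export_overlay",
    "write_overlay_csv",
    "read_plate_csv",
    "fixture_path",
    "grey_myrtle_extracts",
    "grey_myrtle_fractions",
    "grey_myrtle_tree",
]

TREE_SCHEMA = "tba-tree v1"

CAMPAIGN_COLUMNS = [
    "id",
    "label",
    "role",
    "solvent",
    "ic50_value",
    "ic50_unit",
    "ic50_sd",
    "weight_value",
    "weight_unit",
    "dry_source_mass_g",
    "parent_id",
    "retention_time_min",
]

_WEIGHT_FACTORS = {"g": 1.0, "mg": 1e-3}

PathLike = Union[str, Path]


def _parse_float(token: str, column: str, row_number: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise SchemaError(
            f"row {row_number}: cannot parse {column}={token!r} as a number"
        ) from None


def read_campaign_csv(path: PathLike) -> PurificationTree:
    """Read a campaign table into a validated :class:`PurificationTree`.

    Unit conversion happens here: IC50 in any accepted concentration unit,
    weight in g or mg.  Errors carry 1-based data row numbers.  A file with
    a header and no rows yields an empty tree with a warning.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        missing = [c for c in ("id", "role", "weight_value", "weight_unit") if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        nodes: List[MaterialNode] = []
        seen: set = set()
        for row_number, row in enumerate(reader, start=1):
            node_id = (row.get("id") or "").strip()
            if not node_id:
                raise SchemaError(f"row {row_number}: blank id")
            if node_id in seen:
                raise TreeStructureError(f"row {row_number}: duplicate id {node_id!r}")
            seen.add(node_id)

            def get(col: str) -> str:
                return (row.get(col) or "").strip()

            potency: Optional[PotencyEstimate] = None
            if get("ic50_value"):
                value = _parse_float(get("ic50_value"), "ic50_value", row_number)
                unit = get("ic50_unit") or "g/L"
                sd = _parse_float(get("ic50_sd"), "ic50_sd", row_number) if get("ic50_sd") else None
                censored = Censoring.RIGHT if get("censored") == "right" else Censoring.NONE
                try:
                    potency = PotencyEstimate.from_value(
                        value, unit, sd=sd, censored=censored, sd_source="reported" if sd else None
                    )
                except (DomainError, UnitError) as exc:
                    raise type(exc)(f"row {row_number}: {exc}") from None

            weight_g: Optional[float] = None
            if get("weight_value"):
                wu = get("weight_unit") or "g"
                if wu not in _WEIGHT_FACTORS:
                    raise UnitError(f"row {row_number}: unknown weight unit {wu!r}; expected g or mg")
                weight_g = _parse_float(get("weight_value"), "weight_value", row_number) * _WEIGHT_FACTORS[wu]

            try:
                nodes.append(
                    MaterialNode(
                        id=node_id,
                        label=get("label") or node_id,
                        role=MaterialRole(get("role") or "extract"),
                        solvent=get("solvent") or None,
                        weight_g=weight_g,
                        dry_source_mass_g=_parse_float(get("dry_source_mass_g"), "dry_source_mass_g", row_number)
                        if get("dry_source_mass_g") else None,
                        potency=potency,
                        retention_time_min=_parse_float(get("retention_time_min"), "retention_time_min", row_number)
                        if get("retention_time_min") else None,
                        parent_id=get("parent_id") or None,
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"row {row_number}: {exc}") from None
    if not nodes:
        warnings.warn(f"{path}: no data rows, returning empty tree", stacklevel=2)
        return PurificationTree()
    return PurificationTree(nodes)


def write_campaign_csv(tree: PurificationTree, path: PathLike) -> None:
    """Write a tree back to the campaign CSV schema (canonical units: µg/mL IC50, g weight)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CAMPAIGN_COLUMNS + ["censored"])
        writer.writeheader()
        for node in tree:
            p = node.potency
            writer.writerow(
                {
                    "id": node.id,
                    "label": node.label,
                    "role": node.role.value,
                    "solvent": node.solvent or "",
                    "ic50_value": repr(p.ic50) if p else "",
                    "ic50_unit": "g/L" if p else "",
                    "ic50_sd": repr(p.ic50_sd) if p and p.ic50_sd is not None else "",
                    "weight_value": repr(node.weight_g) if node.weight_g is not None else "",
                    "weight_unit": "g" if node.weight_g is not None else "",
                    "dry_source_mass_g": repr(node.dry_source_mass_g)
                    if node.dry_source_mass_g is not None else "",
                    "parent_id": node.parent_id or "",
                    "retention_time_min": repr(node.retention_time_min)
                    if node.retention_time_min is not None else "",
                    "censored": p.censored.value if p and p.censored is Censoring.RIGHT else "",
                }
            )


def _node_to_json(node: MaterialNode) -> Dict[str, object]:
    d: Dict[str, object] = {
        "id": node.id,
        "label": node.label,
        "role": node.role.value,
        "parent_id": node.parent_id,
    }
    if node.solvent is not None:
        d["solvent"] = node.solvent
    if node.weight_g is not None:
        d["weight"] = {"value": node.weight_g, "unit": "g"}
    if node.dry_source_mass_g is not None:
        d["dry_source_mass"] = {"value": node.dry_source_mass_g, "unit": "g"}
    if node.retention_time_min is not None:
        d["retention_time"] = {"value": node.retention_time_min, "unit": "min"}
    p = node.potency
    if p is not None:
        pd: Dict[str, object] = {"ic50": {"value": p.ic50, "unit": "g/L"}, "censored": p.censored.value}
        if p.ic50_sd is not None:
            pd["ic50_sd"] = {"value": p.ic50_sd, "unit": "g/L"}
        if p.n_replicates is not None:
            pd["n_replicates"] = p.n_replicates
        if p.assay_label:
            pd["assay_label"] = p.assay_label
        if p.sd_source:
            pd["sd_source"] = p.sd_source
        d["potency"] = pd
    return d


def _quantity(obj: Dict[str, object], key: str, expected_unit: str) -> Optional[float]:
    if key not in obj:
        return None
    q = obj[key]
    if not isinstance(q, dict) or "value" not in q or "unit" not in q:
        raise SchemaError(f"quantity {key!r} must be an object with 'value' and 'unit'")
    if q["unit"] != expected_unit:
        raise UnitError(f"quantity {key!r}: expected unit {expected_unit!r}, got {q['unit']!r}")
    return float(q["value"])


def write_tree_json(tree: PurificationTree, path: PathLike) -> None:
    """Serialize a tree losslessly under the ``tba-tree v1`` schema."""
    payload = {"schema": TREE_SCHEMA, "nodes": [_node_to_json(n) for n in tree]}
    Path(path).write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")


def read_tree_json(path: PathLike) -> PurificationTree:
    """Read a ``tba-tree v1`` JSON file; unknown schema versions are rejected."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed JSON at line {exc.lineno} column {exc.colno}: {exc.msg}") from None
    if not isinstance(payload, dict) or payload.get("schema") != TREE_SCHEMA:
        raise SchemaError(
            f"{path}: unknown or missing schema version "
            f"{payload.get('schema') if isinstance(payload, dict) else None!r}; expected {TREE_SCHEMA!r}"
        )
    nodes: List[MaterialNode] = []
    for entry in payload.get("nodes", []):
        potency = None
        if "potency" in entry:
            pd = entry["potency"]
            potency = PotencyEstimate(
                ic50=_quantity(pd, "ic50", "g/L"),
                ic50_sd=_quantity(pd, "ic50_sd", "g/L"),
                n_replicates=pd.get("n_replicates"),
                censored=Censoring(pd.get("censored", "none")),
                assay_label=pd.get("assay_label", ""),
                sd_source=pd.get("sd_source"),
            )
        nodes.append(
            MaterialNode(
                id=entry["id"],
                label=entry.get("label", entry["id"]),
                role=MaterialRole(entry.get("role", "extract")),
                solvent=entry.get("solvent"),
                weight_g=_quantity(entry, "weight", "g"),
                dry_source_mass_g=_quantity(entry, "dry_source_mass", "g"),
                potency=potency,
                retention_time_min=_quantity(entry, "retention_time", "min"),
                parent_id=entry.get("parent_id"),
            )
        )
    return PurificationTree(nodes) if nodes else PurificationTree()


# --- report rendering -------------------------------------------------------

_REPORT_FIELDS = [
    ("node_id", "id"),
    ("label", "label"),
    ("ic50_ug_per_ml", "IC50 (µg/mL)"),
    ("edv50_l_per_g", "EDV50 (L/g)"),
    ("weight_g", "Weight (g)"),
    ("tba_l", "TBA (L)"),
    ("dry_source_mass_g", "Dry source (g)"),
    ("tba_per_gram", "TBA/g source (L/g)"),
]


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return ""
    if isinstance(x, float) and x == int(x) and abs(x) < 1e15:
        # keep e.g. 3.0 as "3.0" but avoid 299.40000000000003 artifacts
        return repr(x)
    return repr(x) if isinstance(x, float) else str(x)


def _report_records(report: CampaignReport) -> List[Dict[str, object]]:
    records: List[Dict[str, object]] = []
    for row in report.rows:
        ic50_ug_ml = row.ic50_g_per_l * 1e3 if row.ic50_g_per_l is not None else None
        records.append(
            {
                "node_id": row.node_id,
                "label": row.label,
                "role": row.role,
                "solvent": row.solvent,
                "ic50_ug_per_ml": ic50_ug_ml,
                "edv50_l_per_g": row.edv50_l_per_g,
                "weight_g": row.weight_g,
                "tba_l": row.tba_l,
                "dry_source_mass_g": row.dry_source_mass_g,
                "tba_per_gram": row.tba_per_gram,
                "censored": row.censored,
                "reason": row.reason,
            }
        )
    return records


def render_report(report: CampaignReport, fmt: str = "markdown") -> str:
    """Render a campaign report to ``csv``, ``json`` or ``markdown`` text.

    Pure function of its inputs: identical report and format give
    byte-identical output.  Markdown column order: IC50, EDV50, weight,
    TBA, dry mass, TBA per gram.
    """
    records = _report_records(report)
    if fmt == "json":
        payload = {
            "rows": records,
            "groups": [
                {
                    "parent_id": g.parent_id,
                    "child_ids": list(g.child_ids),
                    "total_weight_g": g.total_weight_g,
                    "total_tba_l": g.total_tba_l,
                    "total_tba_per_gram": g.total_tba_per_gram,
                    "mass_recovery_pct": g.recovery.mass_recovery_pct if g.recovery else None,
                    "tba_recovery_pct": g.recovery.tba_recovery_pct if g.recovery else None,
                    "interaction_class": g.recovery.interaction_class.value
                    if g.recovery and g.recovery.interaction_class else None,
                }
                for g in report.groups
            ],
        }
        return json.dumps(payload, indent=2, ensure_ascii=False) + "\n"
    if fmt == "csv":
        import io as _stdlib_io

        buf = _stdlib_io.StringIO()
        names = [k for k, _ in _REPORT_FIELDS] + ["censored", "reason"]
        writer = csv.DictWriter(buf, fieldnames=names, extrasaction="ignore", lineterminator="\n")
        writer.writeheader()
        for rec in records:
            writer.writerow({k: _fmt(rec[k]) if isinstance(rec[k], float) else (rec[k] if rec[k] is not None else "") for k in names})
        for g in report.groups:
            writer.writerow(
                {
                    "node_id": f"TOTAL:{g.parent_id}",
                    "label": f"total over children of {g.parent_id}",
                    "weight_g": _fmt(g.total_weight_g),
                    "tba_l": _fmt(g.total_tba_l),
                    "tba_per_gram": _fmt(g.total_tba_per_gram),
                }
            )
        return buf.getvalue()
    if fmt == "markdown":
        headers = [h for _, h in _REPORT_FIELDS[1:]]  # drop internal id column
        lines = ["| " + " | ".join(headers) + " |", "|" + "|".join("---" for _ in headers) + "|"]
        for rec in records:
            cells = [str(rec["label"])] + [
                _fmt(rec[k]) for k, _ in _REPORT_FIELDS[2:]
            ]
            lines.append("| " + " | ".join(cells) + " |")
        for g in report.groups:
            cells = [f"total ({g.parent_id})", "", "", _fmt(g.total_weight_g), _fmt(g.total_tba_l), "", _fmt(g.total_tba_per_gram)]
            lines.append("| " + " | ".join(cells) + " |")
            if g.recovery is not None and g.recovery.tba_recovery_pct is not None:
                lines.append(
                    f"| recovery ({g.parent_id}) | mass {round(g.recovery.mass_recovery_pct, 2)}% "
                    f"| TBA {round(g.recovery.tba_recovery_pct, 1)}% "
                    f"| {g.recovery.interaction_class.value if g.recovery.interaction_class else ''} | | | |"
                )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}; expected csv, json or markdown")


def write_report(report: CampaignReport, path: PathLike, fmt: str = "markdown") -> None:
    Path(path).write_text(render_report(report, fmt), encoding="utf-8")


# --- chromatogram overlay ---------------------------------------------------


@dataclass(frozen=True)
class OverlayRecord:
    """One point of an HPLC-chromatogram potency overlay."""

    fraction_id: str
    retention_time_min: float
    edv50_l_per_g: float


def export_overlay(tree: PurificationTree) -> List[OverlayRecord]:
    """Overlay records (retention time vs EDV50) for every node carrying both,
    sorted by retention time.  Nodes lacking either are skipped; an empty
    result triggers a warning."""
    records = [
        OverlayRecord(n.id, n.retention_time_min, n.potency.edv50)
        for n in tree
        if n.retention_time_min is not None and n.potency is not None
    ]
    records.sort(key=lambda r: r.retention_time_min)
    if not records:
        warnings.warn("no nodes carry both retention time and potency; overlay is empty", stacklevel=2)
    return records


def write_overlay_csv(records: Sequence[OverlayRecord], path: PathLike) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["fraction_id", "retention_time_min", "edv50_l_per_g"])
        for r in records:
            writer.writerow([r.fraction_id, repr(r.retention_time_min), repr(r.edv50_l_per_g)])


# --- plate CSV --------------------------------------------------------------


def read_plate_csv(path: PathLike):
    """Read raw serial-dilution readouts: header ``concentration,unit,response_pct,replicate``."""
    from biopotency.potency import DoseResponsePlate

    path = Path(path)
    points = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"concentration", "unit", "response_pct", "replicate"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SchemaError(
                f"{path}: plate CSV needs columns concentration,unit,response_pct,replicate"
            )
        for row_number, row in enumerate(reader, start=1):
            conc = parse_concentration(
                _parse_float(row["concentration"], "concentration", row_number), row["unit"]
            )
            resp = _parse_float(row["response_pct"], "response_pct", row_number)
            points.append((conc, resp, row["replicate"]))
    if not points:
        raise SchemaError(f"{path}: plate CSV has no data rows")
    return DoseResponsePlate(
        points=tuple(points),
        max_tested_concentration=max(c for c, _, _ in points),
    )


# --- packaged fixtures ------------------------------------------------------


def fixture_path(name: str) -> Path:
    """Path to a packaged data file (e.g. ``grey_myrtle_extracts.csv``)."""
    return Path(str(resources.files("biopotency").joinpath("data", name)))


def grey_myrtle_extracts() -> PurificationTree:
    """Grey Myrtle solvent-extract campaign: plant root, one single ethanolic
    extract (75 g leaves) and six sequential extracts (230 g leaves)."""
    return read_campaign_csv(fixture_path("grey_myrtle_extracts.csv"))


def grey_myrtle_fractions() -> PurificationTree:
    """Grey Myrtle HPLC campaign: 4000 mg DCM extract fractionated into 17
    fractions, with retention times for the four pure ones."""
    return read_campaign_csv(fixture_path("grey_myrtle_fractions.csv"))


def grey_myrtle_tree() -> PurificationTree:
    """JSON form of the HPLC campaign (18 nodes)."""
    return read_tree_json(fixture_path("grey_myrtle_tree.json"))
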