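"""Case-mix file formats and report rendering.

A case-mix file carries three blocks: the economic context (threshold,
occupancy, objective, currency label), the options table (one row per
patient group), and the chosen block (a bare group id, or explicit totals).
JSON and YAML nest them; CSV keeps the options table as the body and encodes
context/chosen as ``# key = value`` comment lines above the header, so the
body stays readable by any CSV tool.

All money is stored unit-less; the context-level currency label is applied
at presentation only.  Reports are deterministic: identical inputs render
byte-identical text.
"""

from __future__ import annotations

import io as _io
import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from pydantic import ValidationError

from .approaches import CATALOG, CATALOG_BY_ID, METHODOLOGY_TITLES
from .core import CaseMix, ChosenOption, EconomicContext, OpportunityCostResult, Ranking
from .decision import OptimalityAssessment
from .errors import CaseMixParseError

_OPTION_COLUMNS = ["id", "los_per_patient", "expenditure_per_patient",
                   "revenue_per_patient", "qaly_gain_per_patient", "n_available"]
_CHOSEN_COLUMNS = ["id", "los_total", "expenditure_total", "variable_cost_total",
                   "revenue_total", "qaly_gain_total"]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix == "yml":
        suffix = "yaml"
    if suffix not in {"csv", "json", "yaml"}:
        raise CaseMixParseError(f"cannot infer format from suffix {path.suffix!r}; pass format=")
    return suffix


def _build(payload: dict, where: str) -> tuple[CaseMix, EconomicContext]:
    try:
        context = EconomicContext(**payload.get("context", {}))
        chosen = payload["chosen"]
        if isinstance(chosen, dict):
            chosen = ChosenOption(**chosen)
        case_mix = CaseMix(options=tuple(payload["options"]), chosen=chosen)
    except KeyError as exc:
        raise CaseMixParseError(f"{where}: missing block {exc}") from exc
    except (ValidationError, ValueError) as exc:
        raise CaseMixParseError(f"{where}: {exc}") from exc
    return case_mix, context


def _parse_csv(text: str, where: str) -> tuple[CaseMix, EconomicContext]:
    meta: dict[str, str] = {}
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
    try:
        frame = pd.read_csv(_io.StringIO(text), comment="#", dtype={"id": str})
    except Exception as exc:  # pandas raises several parser error types
        raise CaseMixParseError(f"{where}: {exc}") from exc
    if "id" not in frame.columns:
        raise CaseMixParseError(f"{where}: options table needs an 'id' column")

    options = []
    for row in frame.to_dict(orient="records"):
        options.append({k: v for k, v in row.items() if not (isinstance(v, float) and math.isnan(v))})

    context = {k.split(".", 1)[1]: v for k, v in meta.items() if k.startswith("context.")}
    chosen_fields = {k.split(".", 1)[1]: v for k, v in meta.items() if k.startswith("chosen.")}
    chosen: dict | str
    if chosen_fields:
        chosen = chosen_fields
    elif "chosen" in meta:
        chosen = meta["chosen"]
    else:
        raise CaseMixParseError(f"{where}: no chosen block ('# chosen = <id>' or '# chosen.<field> = ...')")
    return _build({"context": context, "options": options, "chosen": chosen}, where)


def read_case_mix(path: str | Path, format: str | None = None) -> tuple[CaseMix, EconomicContext]:
    """Parse a case-mix file (csv, json or yaml; inferred from the suffix).

    All type invariants are enforced at parse time; violations raise
    :class:`CaseMixParseError` naming the file and offending field.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text(encoding="utf-8")
    where = str(path)
    if fmt == "csv":
        return _parse_csv(text, where)
    if fmt == "json":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CaseMixParseError(f"{where}: invalid JSON: {exc}") from exc
    else:
        try:
            payload = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise CaseMixParseError(f"{where}: invalid YAML: {exc}") from exc
    if not isinstance(payload, dict):
        raise CaseMixParseError(f"{where}: top level must be a mapping")
    return _build(payload, where)


def _drop_none(mapping: dict) -> dict:
    return {k: v for k, v in mapping.items() if v is not None}


def case_mix_to_text(case_mix: CaseMix, context: EconomicContext, format: str = "json") -> str:
    """Serialize; ``read_case_mix`` of the result reproduces the objects exactly."""
    if format == "csv":
        lines = [f"# context.{k} = {v}" for k, v in context.model_dump().items()]
        if isinstance(case_mix.chosen, str):
            lines.append(f"# chosen = {case_mix.chosen}")
        else:
            lines += [f"# chosen.{k} = {v}"
                      for k, v in _drop_none(case_mix.chosen.model_dump()).items()]
        lines.append(",".join(_OPTION_COLUMNS))
        for g in case_mix.options:
            row = g.model_dump()
            lines.append(",".join("" if row[c] is None else str(row[c]) for c in _OPTION_COLUMNS))
        return "\n".join(lines) + "\n"

    payload = {
        "context": context.model_dump(),
        "options": [_drop_none(g.model_dump()) for g in case_mix.options],
        "chosen": case_mix.chosen if isinstance(case_mix.chosen, str)
        else _drop_none(case_mix.chosen.model_dump()),
    }
    if format == "json":
        return json.dumps(payload, indent=2, ensure_ascii=False) + "\n"
    if format == "yaml":
        return yaml.safe_dump(payload, sort_keys=False, allow_unicode=True)
    raise CaseMixParseError(f"unknown case-mix format {format!r}")


def write_case_mix(case_mix: CaseMix, context: EconomicContext,
                   path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    path.write_text(case_mix_to_text(case_mix, context, fmt), encoding="utf-8")


# ---------------------------------------------------------------------------
# Reports


def format_quantity(value: float, unit: str, currency: str = "£", floor_units: bool = False) -> str:
    """Render one result value: money with thousands separators, units trimmed.

    ``floor_units`` floors patient-equivalents to whole displaced patients
    (presentation only; computed values are always fractional).
    """
    if unit == "money":
        if math.isclose(value, round(value), abs_tol=5e-3):
            return f"{currency}{round(value):,}"
        return f"{currency}{value:,.2f}"
    if floor_units and unit == "patient_equivalents":
        value = math.floor(value)
    if math.isclose(value, round(value), abs_tol=1e-9):
        return f"{round(value):,}"
    return f"{value:,.4g}".rstrip("0").rstrip(".")


def _result_display(r: OpportunityCostResult, currency: str, floor_units: bool) -> str:
    text = format_quantity(r.value, r.unit, currency, floor_units)
    if r.secondary_value is not None:  # the variable-cost split pair, never summed
        text += f" & {format_quantity(r.secondary_value, 'bed_days', currency)}"
    return text


def render_results_table(results: Sequence[OpportunityCostResult], currency: str = "£",
                         markdown: bool = False, floor_units: bool = False) -> str:
    """Catalog-shaped report grouped under the four methodology headers."""
    lines: list[str] = []
    if markdown:
        lines.append("| Approach | Description | Value |")
        lines.append("| --- | --- | --- |")
    by_id = {r.approach_id: r for r in results}
    for letter in "ABCD":
        entries = [e for e in CATALOG if e.methodology == letter and e.approach_id in by_id]
        if not entries:
            continue
        title = f"Methodology {letter}: {METHODOLOGY_TITLES[letter]}"
        if markdown:
            lines.append(f"| **{title}** |  |  |")
        else:
            lines.append(title)
        for e in entries:
            value = _result_display(by_id[e.approach_id], currency, floor_units)
            if markdown:
                lines.append(f"| {e.approach_id} | {e.description} | {value} |")
            else:
                lines.append(f"  {e.approach_id:<5} {e.description:<68} {value}")
    return "\n".join(lines) + "\n"


def render_assessment_table(assessment: OptimalityAssessment, currency: str = "£",
                            markdown: bool = False) -> str:
    """Optimality report: per-option totals and the recommended valuation."""
    money = lambda v: format_quantity(v, "money", currency)  # noqa: E731
    cols = list(assessment.options)
    header = ["Option"] + [f"{a.id} (n = {format_quantity(a.n_forgone, 'patient_equivalents', currency)}"
                           + (")" if a is cols[0] else " forgone)") for a in cols]
    rows = [
        ("Expenditure (in total)", [money(a.expenditure_total) for a in cols]),
        ("Benefit (GMB, in total)", [money(a.gross_benefit_total) for a in cols]),
        ("NMB (benefit - expenditure, in total)", [money(a.nmb_total) for a in cols]),
        ("Expenditure + highest NMB forgone", [money(a.expenditure_plus_highest_forgone_nmb) for a in cols]),
    ]
    lines: list[str] = []
    if markdown:
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + " --- |" * len(header))
        for name, values in rows:
            lines.append("| " + " | ".join([name] + values) + " |")
    else:
        widths = [max(len(name) for name, _ in rows)] + [
            max(len(header[k + 1]), *(len(vals[k]) for _, vals in rows)) for k in range(len(cols))
        ]
        lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)))
        for name, values in rows:
            lines.append("  ".join(v.ljust(w) for v, w in zip([name] + values, widths)))
    lines.append("")
    lines.append(f"Optimal option: {assessment.optimal_id}")
    lines.append(f"Chosen is optimal: {'yes' if assessment.chosen_is_optimal else 'no'}")
    lines.append(f"Recommended methodology: {assessment.recommended_methodology}")
    if assessment.true_opportunity_cost is None:
        lines.append("True opportunity cost: no alternative use — not defined")
    else:
        lines.append(f"True opportunity cost: {money(assessment.true_opportunity_cost)}")
    return "\n".join(lines) + "\n"


def write_report(results: Sequence[OpportunityCostResult],
                 assessment: OptimalityAssessment | None = None,
                 format: str = "table", currency: str = "£",
                 floor_units: bool = False) -> str:
    """Render results (and optionally the optimality assessment) as text.

    Formats: ``table`` (plain text), ``markdown``, ``csv`` (results only),
    ``json`` (machine-readable).  Byte-identical for identical inputs.
    """
    if format == "json":
        payload: dict = {"results": [asdict(r) for r in results]}
        if assessment is not None:
            payload["assessment"] = asdict(assessment)
        return json.dumps(payload, indent=2, ensure_ascii=False) + "\n"
    if format == "csv":
        lines = ["approach_id,methodology,description,value,unit,secondary_value"]
        for r in results:
            desc = CATALOG_BY_ID[r.approach_id].description
            secondary = "" if r.secondary_value is None else str(r.secondary_value)
            lines.append(f'{r.approach_id},{r.methodology},"{desc}",{r.value},{r.unit},{secondary}')
        return "\n".join(lines) + "\n"
    if format not in {"table", "markdown"}:
        raise CaseMixParseError(f"unknown report format {format!r}")
    if not results:
        return "No approaches computable for this case mix (all skipped for missing inputs).\n"
    markdown = format == "markdown"
    text = render_results_table(results, currency, markdown, floor_units)
    if assessment is not None:
        text += "\n" + render_assessment_table(assessment, currency, markdown)
    return text


def render_ranking(ranking: Ranking, currency: str = "£") -> str:
    lines = [f"Ranking under objective '{ranking.objective}' (best first):"]
    for pos, (gid, value) in enumerate(ranking.order, start=1):
        lines.append(f"  {pos}. {gid}  (score {value:,.4g})")
    lines.append(f"Best: {ranking.best}")
    lines.append(f"Second-best (excluding chosen): {ranking.second_best or '—'}")
    if ranking.tie_flag:
        lines.append("Warning: tied scores; input order kept.")
    return "\n".join(lines) + "\n"
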