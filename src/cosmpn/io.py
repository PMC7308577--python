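"""CSV readers/writers and flat-text run configuration.

One dialect only: plain comma-separated files with a fixed header row,
``NA`` (or an empty cell) as the missing-value sentinel, floats written
with ``%.17g`` so that write→read is the identity on every field.

Dialects
--------
tubes.csv       ``sample_id,level_exponent,replicate,day,turbid,degradation_ratio_pct,residual_ppmv,initial_ppmv``
samples.csv     ``sample_id,sample_type,water_content_pct_wet,pH,toc_pct,rate_constant``
timecourse.csv  ``series_id,time_h,cos_ppmv,below_detection``
estimates.csv   ``sample_id,target,pattern,levels,lambda,mpn_per_g_dry,ci_low,ci_high,status``
config          flat ``key = value`` lines, ``#`` comments; keys are RunConfig
                field names (dilution-design fields prefixed ``design.``).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import ParseError, ValidationError
from .models import (
    COSTimeCourse,
    DilutionDesign,
    RunConfig,
    SampleMetadata,
    TubeObservation,
)

PathLike = Union[str, Path]

TUBE_COLUMNS = (
    "sample_id",
    "level_exponent",
    "replicate",
    "day",
    "turbid",
    "degradation_ratio_pct",
    "residual_ppmv",
    "initial_ppmv",
)
SAMPLE_COLUMNS = (
    "sample_id",
    "sample_type",
    "water_content_pct_wet",
    "pH",
    "toc_pct",
    "rate_constant",
)
TIMECOURSE_COLUMNS = ("series_id", "time_h", "cos_ppmv", "below_detection")
ESTIMATE_COLUMNS = (
    "sample_id",
    "target",
    "pattern",
    "levels",
    "lambda",
    "mpn_per_g_dry",
    "ci_low",
    "ci_high",
    "status",
)

NA = "NA"
#: degradation ratios above this are rejected; (100, 120] kept with a warning
RATIO_CEILING_PCT = 120.0


def _fmt(x) -> str:
    """Render one cell: NA for missing, %.17g for floats (lossless)."""
    if x is None:
        return NA
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, float):
        return format(x, ".17g")
    return str(x)


def _parse_float(cell: str, row: int, col: str) -> Optional[float]:
    cell = cell.strip()
    if cell in ("", NA, "-", "—"):
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise ParseError(f"row {row}: column {col!r}: not a number: {cell!r}") from exc


def _parse_bool(cell: str, row: int, col: str) -> Optional[bool]:
    cell = cell.strip()
    if cell in ("", NA, "-", "—"):
        return None
    if cell in ("0", "1"):
        return cell == "1"
    raise ParseError(f"row {row}: column {col!r}: expected 0/1/NA, got {cell!r}")


def _check_header(header: Sequence[str], expected: Sequence[str], path) -> None:
    if tuple(h.strip() for h in header) != tuple(expected):
        raise ParseError(
            f"{path}: header {header!r} does not match the declared dialect "
            f"{list(expected)!r}"
        )


# ---------------------------------------------------------------------------
# tubes.csv


def read_tube_table(
    path: PathLike, design: DilutionDesign
) -> list[TubeObservation]:
    """Read a tube-observation table, validating against the dilution design.

    Missing cells (``NA``/empty, or a table em-dash) become ``None``, never
    zero.  Ratios in (100, 120] are retained with a warning (GC overshoot);
    ratios outside [0, 120] raise.  Rows with no measurement at all are
    skipped with a warning.
    """
    path = Path(path)
    out: list[TubeObservation] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (no header)") from None
        _check_header(header, TUBE_COLUMNS, path)
        for i, rowvals in enumerate(reader, start=2):
            if not rowvals or all(not c.strip() for c in rowvals):
                continue
            if len(rowvals) != len(TUBE_COLUMNS):
                raise ParseError(
                    f"row {i}: expected {len(TUBE_COLUMNS)} fields, "
                    f"got {len(rowvals)}"
                )
            rec = dict(zip(TUBE_COLUMNS, rowvals))
            level = _parse_float(rec["level_exponent"], i, "level_exponent")
            replicate = _parse_float(rec["replicate"], i, "replicate")
            day = _parse_float(rec["day"], i, "day")
            if level is None or replicate is None or day is None:
                raise ParseError(f"row {i}: level/replicate/day must be present")
            level = int(level)
            replicate = int(replicate)
            if level not in design.level_exponents:
                raise ValidationError(
                    f"row {i}: unknown level exponent {level} "
                    f"(design has {list(design.level_exponents)})"
                )
            if not 1 <= replicate <= design.tubes_per_level:
                raise ValidationError(
                    f"row {i}: replicate {replicate} outside "
                    f"1..{design.tubes_per_level}"
                )
            turbid = _parse_bool(rec["turbid"], i, "turbid")
            ratio = _parse_float(rec["degradation_ratio_pct"], i, "degradation_ratio_pct")
            residual = _parse_float(rec["residual_ppmv"], i, "residual_ppmv")
            initial = _parse_float(rec["initial_ppmv"], i, "initial_ppmv")
            if ratio is not None:
                if not 0.0 <= ratio <= RATIO_CEILING_PCT:
                    raise ValidationError(
                        f"row {i}: degradation ratio {ratio} outside "
                        f"[0, {RATIO_CEILING_PCT}]"
                    )
                if ratio > 100.0:
                    warnings.warn(
                        f"row {i}: ratio {ratio}% exceeds 100% "
                        "(measurement overshoot); kept as-is",
                        stacklevel=2,
                    )
            if turbid is None and ratio is None and residual is None:
                warnings.warn(
                    f"row {i}: tube {level}-{replicate} day {day:g} has no "
                    "measurement; skipped",
                    stacklevel=2,
                )
                continue
            out.append(
                TubeObservation(
                    level_exponent=level,
                    replicate=replicate,
                    day=day,
                    turbid=turbid,
                    degradation_ratio_pct=ratio,
                    residual_ppmv=residual,
                    initial_ppmv=initial,
                )
            )
    return out


def write_tube_table(
    observations: Iterable[TubeObservation], path: PathLike, sample_id: str = "sample"
) -> None:
    """Write observations in the tubes.csv dialect (lossless round trip)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TUBE_COLUMNS)
        for o in observations:
            w.writerow(
                [
                    sample_id,
                    o.level_exponent,
                    o.replicate,
                    _fmt(float(o.day)),
                    _fmt(o.turbid),
                    _fmt(o.degradation_ratio_pct),
                    _fmt(o.residual_ppmv),
                    _fmt(o.initial_ppmv),
                ]
            )


# ---------------------------------------------------------------------------
# samples.csv


def read_samples(path: PathLike) -> pd.DataFrame:
    """Read sample metadata/rate table into a DataFrame (NA-aware)."""
    path = Path(path)
    df = pd.read_csv(path, na_values=[NA], keep_default_na=True)
    _check_header(df.columns, SAMPLE_COLUMNS, path)
    return df


def metadata_from_samples(
    df: pd.DataFrame,
    mass_used_g_wet: float = 4.0,
    volume_ml: float = 10.0,
) -> dict[str, SampleMetadata]:
    """Build :class:`SampleMetadata` per sample from a samples.csv frame.

    The table does not carry the assay amounts, so the standard amounts are
    supplied here: ``mass_used_g_wet`` grams wet for solid samples and
    ``volume_ml`` millilitres for water samples.
    """
    out: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        is_water = row["sample_type"] == "pond_water"
        wc = row["water_content_pct_wet"]
        out[str(row["sample_id"])] = SampleMetadata(
            sample_id=str(row["sample_id"]),
            sample_type=str(row["sample_type"]),
            water_content=0.0 if pd.isna(wc) else float(wc) / 100.0,
            pH=float(row["pH"]),
            toc=None if pd.isna(row["toc_pct"]) else float(row["toc_pct"]),
            mass_used_g_wet=None if is_water else mass_used_g_wet,
            volume_ml=volume_ml if is_water else None,
        )
    return out


def write_samples(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False, na_rep=NA, float_format="%.17g")


# ---------------------------------------------------------------------------
# timecourse.csv


def read_timecourses(path: PathLike) -> dict[str, COSTimeCourse]:
    """Read one or more COS time courses keyed by series_id."""
    path = Path(path)
    df = pd.read_csv(path, na_values=[NA])
    _check_header(df.columns, TIMECOURSE_COLUMNS, path)
    out: dict[str, COSTimeCourse] = {}
    for sid, grp in df.groupby("series_id", sort=False):
        grp = grp.sort_values("time_h")
        out[str(sid)] = COSTimeCourse(
            times_h=tuple(grp["time_h"].astype(float)),
            concentrations_ppmv=tuple(grp["cos_ppmv"].astype(float)),
            below_detection=tuple(grp["below_detection"].fillna(0).astype(int) == 1),
            series_id=str(sid),
        )
    return out


def write_timecourses(courses: Iterable[COSTimeCourse], path: PathLike) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TIMECOURSE_COLUMNS)
        for tc in courses:
            for t, c, b in zip(tc.times_h, tc.concentrations_ppmv, tc.below_detection):
                w.writerow([tc.series_id, _fmt(t), _fmt(c), "1" if b else "0"])


# ---------------------------------------------------------------------------
# estimates.csv


def write_results(estimates: Sequence, path: PathLike) -> None:
    """Write MPN estimates (lossless round trip; NA for undefined bounds).

    Patterns and level windows are dash-joined integers (``3-1-1``,
    ``7-8-9``).  ``status`` carries the ``above_range``/``below_range``
    sentinels for degenerate patterns.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ESTIMATE_COLUMNS)
        for e in estimates:
            w.writerow(
                [
                    e.sample_id,
                    e.target,
                    "-".join(str(int(p)) for p in e.pattern),
                    "-".join(str(int(l)) for l in e.selected_levels),
                    _fmt(e.lambda_per_ref_tube),
                    _fmt(e.mpn_per_g_dry),
                    _fmt(e.ci_low),
                    _fmt(e.ci_high),
                    e.status,
                ]
            )


def read_results(path: PathLike) -> list:
    """Read estimates.csv back into :class:`~cosmpn.mpn.MPNEstimate` objects."""
    from .mpn import MPNEstimate  # local import: avoid cycle

    path = Path(path)
    out = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        _check_header(header, ESTIMATE_COLUMNS, path)
        for i, rowvals in enumerate(reader, start=2):
            if not rowvals:
                continue
            rec = dict(zip(ESTIMATE_COLUMNS, rowvals))
            out.append(
                MPNEstimate(
                    sample_id=rec["sample_id"],
                    target=rec["target"],
                    pattern=tuple(int(x) for x in rec["pattern"].split("-")),
                    selected_levels=tuple(int(x) for x in rec["levels"].split("-")),
                    lambda_per_ref_tube=_parse_float(rec["lambda"], i, "lambda"),
                    mpn_per_g_dry=_parse_float(rec["mpn_per_g_dry"], i, "mpn_per_g_dry"),
                    ci_low=_parse_float(rec["ci_low"], i, "ci_low"),
                    ci_high=_parse_float(rec["ci_high"], i, "ci_high"),
                    status=rec["status"],
                )
            )
    return out


# ---------------------------------------------------------------------------
# config


def write_config(cfg: RunConfig, path: PathLike) -> None:
    """Write a RunConfig as flat ``key = value`` text."""
    path = Path(path)
    lines = []
    for f in dc_fields(cfg):
        val = getattr(cfg, f.name)
        if f.name == "design":
            for g in dc_fields(val):
                gv = getattr(val, g.name)
                if g.name == "level_exponents":
                    gv = ",".join(str(x) for x in gv)
                lines.append(f"design.{g.name} = {gv}")
        elif f.name == "measurement_days":
            lines.append(f"{f.name} = " + ",".join(format(d, 'g') for d in val))
        elif f.name == "hydrolysis_anchors":
            lines.append(
                f"{f.name} = "
                + ",".join(f"{p:g}:{frac:g}" for p, frac in val)
            )
        else:
            lines.append(f"{f.name} = {_fmt(val)}")
    path.write_text("\n".join(lines) + "\n")


def read_config(path: PathLike) -> RunConfig:
    """Parse a flat key/value config file into a RunConfig."""
    path = Path(path)
    kv: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}: line {lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        kv[key] = val

    design_kwargs = {}
    run_kwargs = {}
    for key, val in kv.items():
        if key.startswith("design."):
            name = key[len("design."):]
            if name == "level_exponents":
                design_kwargs[name] = tuple(int(x) for x in val.split(","))
            elif name in ("tubes_per_level", "dilution_base"):
                design_kwargs[name] = int(val)
            else:
                design_kwargs[name] = float(val)
        elif key == "measurement_days":
            run_kwargs[key] = tuple(float(x) for x in val.split(","))
        elif key == "hydrolysis_anchors":
            run_kwargs[key] = tuple(
                tuple(float(x) for x in pair.split(":")) for pair in val.split(",")
            )
        elif key in (
            "positivity_threshold_pct",
            "cos_initial_ppmv",
            "assay_duration_h",
            "detection_limit_ppmv",
        ):
            run_kwargs[key] = float(val)
        else:
            raise ParseError(f"{path}: unknown config key {key!r}")
    if design_kwargs:
        run_kwargs["design"] = DilutionDesign(**design_kwargs)
    return RunConfig(**run_kwargs)
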