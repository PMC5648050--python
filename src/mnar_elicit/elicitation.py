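"""Structured records of expert elicitation sessions.

An elicitation session asks each expert for three normal distributions on a
quality-of-life (QoL) score scale running from -20 to 100 (the EQ-5D utility
scale multiplied by 100): the likely score of a patient with a *missing*
outcome in the open-repair arm, the same for the endovascular (eEVAR) arm,
and the eEVAR score again *conditional* on a stated open-arm score.  The
third answer carries the information needed to correlate the two sensitivity
parameters downstream.

This module defines the record types, validates them against the scale
invariants, and reads/writes them as JSON (full fidelity) or flat CSV (one
row per expert).
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

from scipy.stats import norm

__all__ = [
    "QOL_MIN",
    "QOL_MAX",
    "UTILITY_SCALE",
    "Role",
    "Venue",
    "ElicitedNormal",
    "ConditionalElicitation",
    "ExpertResponse",
    "AnchorScores",
    "ElicitationSet",
    "ValidationPolicy",
    "Violation",
    "ElicitationError",
    "validate_response",
    "read_responses",
    "write_responses",
    "exclude_flagged",
]

#: Bounds of the elicitation scale (EQ-5D utility x 100; worse-than-death
#: states are negative, hence the -20 floor).
QOL_MIN = -20.0
QOL_MAX = 100.0
#: Divisor mapping the elicitation scale back to the 0-1 utility scale.
UTILITY_SCALE = 100.0


class ElicitationError(ValueError):
    """Raised when a response file cannot be parsed or validated."""


class Role(str, Enum):
    DOCTOR = "doctor"
    NURSE = "nurse"
    OTHER = "other"


class Venue(str, Enum):
    EMAIL = "email"
    CONFERENCE = "conference"
    FACE_TO_FACE = "face_to_face"


@dataclass(frozen=True)
class ElicitedNormal:
    """One slider answer: a normal belief on the -20..100 QoL scale.

    Parameters
    ----------
    mode : float
        Most likely QoL score (the normal mean).
    sd : float
        The expert's uncertainty, as the normal standard deviation; must be
        strictly positive.
    """

    mode: float
    sd: float

    def mass_outside_scale(self) -> float:
        """Probability mass the normal places outside [-20, 100]."""
        lo = norm.cdf(QOL_MIN, loc=self.mode, scale=self.sd)
        hi = norm.sf(QOL_MAX, loc=self.mode, scale=self.sd)
        return float(lo + hi)


@dataclass(frozen=True)
class ConditionalElicitation:
    """The eEVAR belief elicited after a specific open-arm score was shown."""

    conditioning_value: float
    distribution: ElicitedNormal


@dataclass(frozen=True)
class AnchorScores:
    """Displayed scores of the *observed* typical patient in each arm.

    These anchor the elicited missing-patient scores: the sensitivity
    parameter for an arm is (elicited score - anchor) / 100.  They are trial
    configuration, not elicited quantities, and have no default.
    """

    open_observed: float
    evar_observed: float


@dataclass(frozen=True)
class ExpertResponse:
    """One expert's complete elicitation session."""

    expert_id: str
    role: Role
    open_missing: ElicitedNormal
    evar_missing: ElicitedNormal
    evar_given_open: ConditionalElicitation
    venue: Venue = Venue.EMAIL
    years_band: str = ""
    familiarity: str = ""
    #: Optional categorical correlation statement ("positive"/"zero"/
    #: "negative") an expert may have given alongside the sliders.
    correlation_statement: Optional[str] = None
    complete: bool = True


@dataclass
class ElicitationSet:
    """A panel of expert responses plus the anchors they were shown."""

    responses: list[ExpertResponse]
    anchors: Optional[AnchorScores] = None
    schema_version: str = "1.0"

    def __post_init__(self) -> None:
        ids = [r.expert_id for r in self.responses]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ElicitationError(f"duplicate expert_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.responses)

    def by_role(self, role: Role) -> list[ExpertResponse]:
        return [r for r in self.responses if r.role == role]


@dataclass(frozen=True)
class ValidationPolicy:
    """Thresholds separating hard violations from soft flags.

    ``uncertainty_flag_sd`` marks near-total-uncertainty answers (an SD this
    large spans most of the 120-unit scale); such responses are flagged for
    an explicit analyst decision, never silently dropped.
    ``outside_mass_warn`` flags normals placing more than this fraction of
    their mass outside the scale bounds.
    """

    uncertainty_flag_sd: float = 40.0
    outside_mass_warn: float = 0.05


@dataclass(frozen=True)
class Violation:
    field: str
    message: str
    severity: str = "error"  # "error" or "warning"
    code: str = "invalid"  # e.g. out_of_range, nonpositive_sd, uncertainty, outside_mass

    @property
    def is_error(self) -> bool:
        return self.severity == "error"


def _check_normal(name: str, d: ElicitedNormal, policy: ValidationPolicy) -> list[Violation]:
    out: list[Violation] = []
    if not math.isfinite(d.mode) or not (QOL_MIN <= d.mode <= QOL_MAX):
        out.append(
            Violation(
                f"{name}.mode",
                f"mode {d.mode!r} out of range [{QOL_MIN}, {QOL_MAX}]",
                code="out_of_range",
            )
        )
    if not math.isfinite(d.sd) or d.sd <= 0:
        out.append(Violation(f"{name}.sd", f"sd {d.sd!r} must be > 0", code="nonpositive_sd"))
        return out
    if d.sd > policy.uncertainty_flag_sd:
        out.append(
            Violation(
                f"{name}.sd",
                f"sd {d.sd} exceeds near-total-uncertainty threshold "
                f"{policy.uncertainty_flag_sd}",
                severity="warning",
                code="uncertainty",
            )
        )
    if math.isfinite(d.mode) and d.mass_outside_scale() > policy.outside_mass_warn:
        out.append(
            Violation(
                name,
                f"more than {policy.outside_mass_warn:.0%} of the normal mass "
                f"lies outside [{QOL_MIN}, {QOL_MAX}]",
                severity="warning",
                code="outside_mass",
            )
        )
    return out


def validate_response(
    r: ExpertResponse, policy: ValidationPolicy | None = None
) -> list[Violation]:
    """Return all invariant violations for one response.

    Violations are data, not exceptions: the list is empty iff the response
    satisfies every hard invariant; soft issues come back with severity
    ``"warning"``.
    """
    policy = policy or ValidationPolicy()
    out: list[Violation] = []
    if not r.expert_id:
        out.append(Violation("expert_id", "expert_id must be non-empty"))
    if not isinstance(r.role, Role):
        out.append(Violation("role", f"role {r.role!r} not one of {[x.value for x in Role]}"))
    out += _check_normal("open_missing", r.open_missing, policy)
    out += _check_normal("evar_missing", r.evar_missing, policy)
    cv = r.evar_given_open.conditioning_value
    if not math.isfinite(cv) or not (QOL_MIN <= cv <= QOL_MAX):
        out.append(
            Violation(
                "evar_given_open.conditioning_value",
                f"conditioning value {cv!r} out of range [{QOL_MIN}, {QOL_MAX}]",
            )
        )
    out += _check_normal("evar_given_open.distribution", r.evar_given_open.distribution, policy)
    if r.correlation_statement is not None and r.correlation_statement not in (
        "positive",
        "zero",
        "negative",
    ):
        out.append(
            Violation(
                "correlation_statement",
                f"{r.correlation_statement!r} not one of positive/zero/negative",
            )
        )
    return out


def is_flagged(
    r: ExpertResponse,
    policy: ValidationPolicy | None = None,
    codes: tuple[str, ...] = ("uncertainty",),
) -> bool:
    """True when the response carries a warning flag with one of ``codes``."""
    return any(
        not v.is_error and v.code in codes for v in validate_response(r, policy)
    )


def exclude_flagged(
    eset: ElicitationSet,
    policy: ValidationPolicy | None = None,
    codes: tuple[str, ...] = ("uncertainty",),
) -> tuple[ElicitationSet, list[str]]:
    """Explicit opt-in filter removing flagged responses.

    By default only near-total-uncertainty responses are removed (softer
    flags such as scale-edge mass are informational).  Returns the filtered
    set and the ids that were dropped, so the exclusion is always visible in
    the analysis record.
    """
    kept, dropped = [], []
    for r in eset.responses:
        (dropped if is_flagged(r, policy, codes) else kept).append(r)
    return (
        ElicitationSet(kept, anchors=eset.anchors, schema_version=eset.schema_version),
        [r.expert_id for r in dropped],
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

_CSV_FIELDS = [
    "expert_id",
    "role",
    "venue",
    "years_band",
    "familiarity",
    "open_mode",
    "open_sd",
    "evar_mode",
    "evar_sd",
    "cond_value",
    "cond_mode",
    "cond_sd",
    "correlation_statement",
    "complete",
    "anchor_open",
    "anchor_evar",
]


def _response_to_dict(r: ExpertResponse) -> dict:
    d = asdict(r)
    d["role"] = r.role.value
    d["venue"] = r.venue.value
    return d


def _response_from_dict(d: dict, where: str) -> ExpertResponse:
    try:
        return ExpertResponse(
            expert_id=str(d["expert_id"]),
            role=Role(d["role"]),
            venue=Venue(d.get("venue", "email")),
            years_band=d.get("years_band", ""),
            familiarity=d.get("familiarity", ""),
            open_missing=ElicitedNormal(**d["open_missing"]),
            evar_missing=ElicitedNormal(**d["evar_missing"]),
            evar_given_open=ConditionalElicitation(
                conditioning_value=d["evar_given_open"]["conditioning_value"],
                distribution=ElicitedNormal(**d["evar_given_open"]["distribution"]),
            ),
            correlation_statement=d.get("correlation_statement"),
            complete=bool(d.get("complete", True)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ElicitationError(f"{where}: malformed response record: {exc}") from exc


def _infer_format(source: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    suffix = Path(source).suffix.lower()
    return "csv" if suffix == ".csv" else "json"


def read_responses(
    source: Union[str, Path, IO[str]],
    format: Optional[str] = None,
    policy: ValidationPolicy | None = None,
) -> ElicitationSet:
    """Read and validate an elicitation set from JSON or CSV.

    Every record must pass :func:`validate_response` with no hard violations;
    the first offending record aborts the read with a located error message.
    Warning flags do not block reading.
    """
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
        fmt = format or "json"
        name = "<stream>"
    else:
        path = Path(source)
        if not path.exists():
            raise ElicitationError(f"no such file: {path}")
        text = path.read_text(encoding="utf-8")
        fmt = _infer_format(path, format)
        name = str(path)

    if fmt == "json":
        eset = _read_json(text, name)
    elif fmt == "csv":
        eset = _read_csv(text, name)
    else:
        raise ElicitationError(f"unknown format {fmt!r} (expected json or csv)")

    for i, r in enumerate(eset.responses):
        errors = [v for v in validate_response(r, policy) if v.is_error]
        if errors:
            v = errors[0]
            raise ElicitationError(
                f"{name}: record {i} (expert_id={r.expert_id!r}), "
                f"field {v.field}: {v.message}"
            )
    return eset


def _read_json(text: str, name: str) -> ElicitationSet:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ElicitationError(f"{name}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(payload, dict) or "responses" not in payload:
        raise ElicitationError(f"{name}: expected an object with a 'responses' array")
    responses = [
        _response_from_dict(d, f"{name}: record {i}")
        for i, d in enumerate(payload["responses"])
    ]
    anchors = None
    if payload.get("anchors") is not None:
        a = payload["anchors"]
        try:
            anchors = AnchorScores(
                open_observed=float(a["open_observed"]),
                evar_observed=float(a["evar_observed"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ElicitationError(f"{name}: malformed anchors: {exc}") from exc
    return ElicitationSet(
        responses, anchors=anchors, schema_version=str(payload.get("schema_version", "1.0"))
    )


def _read_csv(text: str, name: str) -> ElicitationSet:
    reader = csv.DictReader(io.StringIO(text))
    responses = []
    anchors: Optional[AnchorScores] = None
    for i, row in enumerate(reader):
        where = f"{name}: line {i + 2}"
        try:
            responses.append(
                ExpertResponse(
                    expert_id=row["expert_id"],
                    role=Role(row["role"]),
                    venue=Venue(row.get("venue") or "email"),
                    years_band=row.get("years_band", "") or "",
                    familiarity=row.get("familiarity", "") or "",
                    open_missing=ElicitedNormal(float(row["open_mode"]), float(row["open_sd"])),
                    evar_missing=ElicitedNormal(float(row["evar_mode"]), float(row["evar_sd"])),
                    evar_given_open=ConditionalElicitation(
                        conditioning_value=float(row["cond_value"]),
                        distribution=ElicitedNormal(float(row["cond_mode"]), float(row["cond_sd"])),
                    ),
                    correlation_statement=(row.get("correlation_statement") or None),
                    complete=(row.get("complete", "true").strip().lower() in ("1", "true", "yes")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ElicitationError(f"{where}: malformed row: {exc}") from exc
        if anchors is None and row.get("anchor_open") not in (None, ""):
            anchors = AnchorScores(float(row["anchor_open"]), float(row["anchor_evar"]))
    return ElicitationSet(responses, anchors=anchors)


def write_responses(
    eset: ElicitationSet,
    sink: Union[str, Path, IO[str]],
    format: Optional[str] = None,
) -> None:
    """Write an elicitation set; read_responses(write_responses(s)) == s."""
    own = not hasattr(sink, "write")
    if own:
        path = Path(sink)
        fmt = _infer_format(path, format)
        handle: IO[str] = path.open("w", encoding="utf-8", newline="")
    else:
        handle = sink  # type: ignore[assignment]
        fmt = format or "json"
    try:
        if fmt == "json":
            payload = {
                "schema_version": eset.schema_version,
                "anchors": asdict(eset.anchors) if eset.anchors else None,
                "responses": [_response_to_dict(r) for r in eset.responses],
            }
            json.dump(payload, handle, indent=2, ensure_ascii=False)
        elif fmt == "csv":
            writer = csv.DictWriter(handle, fieldnames=_CSV_FIELDS)
            writer.writeheader()
            for r in eset.responses:
                writer.writerow(
                    {
                        "expert_id": r.expert_id,
                        "role": r.role.value,
                        "venue": r.venue.value,
                        "years_band": r.years_band,
                        "familiarity": r.familiarity,
                        "open_mode": repr(r.open_missing.mode),
                        "open_sd": repr(r.open_missing.sd),
                        "evar_mode": repr(r.evar_missing.mode),
                        "evar_sd": repr(r.evar_missing.sd),
                        "cond_value": repr(r.evar_given_open.conditioning_value),
                        "cond_mode": repr(r.evar_given_open.distribution.mode),
                        "cond_sd": repr(r.evar_given_open.distribution.sd),
                        "correlation_statement": r.correlation_statement or "",
                        "complete": str(r.complete).lower(),
                        "anchor_open": "" if eset.anchors is None else repr(eset.anchors.open_observed),
                        "anchor_evar": "" if eset.anchors is None else repr(eset.anchors.evar_observed),
                    }
                )
        else:
            raise ElicitationError(f"unknown format {fmt!r} (expected json or csv)")
    finally:
        if own:
            handle.close()
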