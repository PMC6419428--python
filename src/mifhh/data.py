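"""Data model for multiple-informant family health history (MIFHH) report tables.

The unit of observation is the *dyad*: one informant's account of one family
member's disease status, together with dyad-level attributes (degree of
relation, gender homophily, perceived health behaviours of the member) and
informant-level attributes (gender, obesity status).  A dataset is a long
table of such dyads, several of which may report on the same family member.

This module reads/writes the delimited-text representation, validates the
data-model invariants, and assembles the design matrices consumed by the
hierarchical sampler: the stacked response ``y``, the fixed-effect matrix
``X`` (level 1, dyadic), the random-coefficient matrix ``W`` (level 2,
informant attributes), and the cluster index ``g`` mapping each dyad to its
informant or family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dataclass_fields
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from mifhh.exceptions import (
    ConfigurationError,
    DegenerateInputError,
    FormatError,
    ValidationError,
)

#: canonical CSV column -> DyadReport attribute
COLUMN_TO_FIELD: dict[str, str] = {
    "family_id": "family_id",
    "informant_id": "informant_id",
    "member_id": "member_id",
    "report": "status",
    "degree": "degree_of_relation",
    "same_gender": "same_gender",
    "smokes": "smokes",
    "alcohol": "uses_alcohol",
    "healthy_weight": "healthy_weight",
    "informant_female": "informant_female",
    "informant_obese": "informant_obese",
}

FIELD_TO_COLUMN: dict[str, str] = {v: k for k, v in COLUMN_TO_FIELD.items()}

#: attribute names usable as model covariates
COVARIATE_FIELDS: tuple[str, ...] = (
    "degree_of_relation",
    "same_gender",
    "smokes",
    "uses_alcohol",
    "healthy_weight",
    "informant_female",
    "informant_obese",
)

#: binary-coded covariates (everything except the degree count)
_BINARY_FIELDS = tuple(f for f in COVARIATE_FIELDS if f != "degree_of_relation")


@dataclass(frozen=True)
class DyadReport:
    """One informant's report on one family member.

    ``status`` is the reported disease status (1 affected, 0 unaffected) or
    ``None`` for a missing / "don't know" report.  ``degree_of_relation`` is a
    small non-negative integer with 0 denoting a self-report; all other
    covariates are 0/1 coded.  ``informant_obese`` follows the source coding
    BMI > 25.
    """

    family_id: str
    informant_id: str
    member_id: str
    status: Optional[int]
    degree_of_relation: int = 0
    same_gender: int = 0
    smokes: int = 0
    uses_alcohol: int = 0
    healthy_weight: int = 0
    informant_female: int = 0
    informant_obese: int = 0

    @property
    def is_missing(self) -> bool:
        return self.status is None

    @property
    def is_self_report(self) -> bool:
        return self.informant_id == self.member_id

    def validate(self) -> None:
        if self.status not in (0, 1, None):
            raise ValidationError(
                f"status must be 0, 1 or missing; got {self.status!r} for dyad "
                f"({self.informant_id}, {self.member_id})"
            )
        if self.degree_of_relation < 0:
            raise ValidationError(
                f"degree_of_relation must be >= 0; got {self.degree_of_relation} for dyad "
                f"({self.informant_id}, {self.member_id})"
            )
        for name in _BINARY_FIELDS:
            value = getattr(self, name)
            if value not in (0, 1):
                raise ValidationError(
                    f"{name} must be 0/1; got {value!r} for dyad "
                    f"({self.informant_id}, {self.member_id})"
                )


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter each level, and how observations are clustered.

    ``cluster_level`` selects the level-2 covariance structure: ``"informant"``
    models within-informant covariation (one random-coefficient vector per
    informant), ``"family"`` models within- and between-informant covariation
    (one vector per family), and ``"none"`` is the non-hierarchical null
    baseline.  ``estimate_sigma2`` toggles sampling the over-dispersion
    variance versus fixing it to 1.  The default fixes it: with a single
    Bernoulli trial per row the per-observation variance is not identified
    by the likelihood (each latent logit can drift to match its own outcome),
    so under a vague prior the sigma^2 chain wanders upward and inflates the
    fixed-effect scale.
    """

    name: str = "model"
    level1_covariates: tuple[str, ...] = ()
    level2_covariates: tuple[str, ...] = ()
    cluster_level: str = "informant"
    estimate_sigma2: bool = False

    def __post_init__(self) -> None:
        if self.cluster_level not in ("informant", "family", "none"):
            raise ConfigurationError(
                f"cluster_level must be 'informant', 'family' or 'none'; got {self.cluster_level!r}"
            )
        if self.cluster_level == "none" and self.level2_covariates:
            raise ConfigurationError(
                "the non-hierarchical null model (cluster_level='none') cannot carry "
                "level-2 covariates"
            )
        for name in (*self.level1_covariates, *self.level2_covariates):
            if name not in COVARIATE_FIELDS:
                raise ConfigurationError(
                    f"unknown covariate {name!r}; choose from {COVARIATE_FIELDS}"
                )

    @property
    def p(self) -> int:
        """Fixed-effect count including the intercept."""
        return 1 + len(self.level1_covariates)

    @property
    def q(self) -> int:
        """Random-coefficient count including the random intercept (0 for the null)."""
        if self.cluster_level == "none":
            return 0
        return 1 + len(self.level2_covariates)


def standard_model_specs(cluster_level: str = "informant") -> dict[str, ModelSpec]:
    """The null baseline and the M1–M5 candidate series under one clustering.

    M1 is intercepts-only at both levels; M2 adds degree of relation and
    gender homophily (level 1); M3 adds informant gender and obesity
    (level 2); M4 adds the informant's perception of the member's health
    behaviours (level 1); M5 combines M3 and M4.
    """
    behaviour = ("smokes", "uses_alcohol", "healthy_weight")
    dyadic = ("degree_of_relation", "same_gender")
    informant_attrs = ("informant_female", "informant_obese")
    return {
        "null": ModelSpec(name="null", cluster_level="none", estimate_sigma2=False),
        "M1": ModelSpec(name="M1", cluster_level=cluster_level),
        "M2": ModelSpec(name="M2", level1_covariates=dyadic, cluster_level=cluster_level),
        "M3": ModelSpec(
            name="M3",
            level1_covariates=dyadic,
            level2_covariates=informant_attrs,
            cluster_level=cluster_level,
        ),
        "M4": ModelSpec(
            name="M4",
            level1_covariates=dyadic + behaviour,
            cluster_level=cluster_level,
        ),
        "M5": ModelSpec(
            name="M5",
            level1_covariates=dyadic + behaviour,
            level2_covariates=informant_attrs,
            cluster_level=cluster_level,
        ),
    }


@dataclass
class DesignMatrices:
    """Stacked model inputs for one dataset under one :class:`ModelSpec`.

    Rows are canonically ordered by (family_id, member_id, informant_id) so
    that the design — and hence any fixed-seed posterior — is invariant to
    the order records arrive in.  ``W`` and ``g`` are ``None`` for the
    non-hierarchical null model.
    """

    y: np.ndarray
    X: np.ndarray
    W: Optional[np.ndarray]
    g: Optional[np.ndarray]
    dyad_index: pd.DataFrame
    spec: ModelSpec
    n_clusters: int
    n_informants: int
    n_members: int
    n_missing_excluded: int = 0

    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return 0 if self.W is None else self.W.shape[1]

    @property
    def C(self) -> int:
        return self.n_clusters


def _parse_binary(raw: object, column: str, line: int, errors: list[str]) -> int:
    try:
        value = int(float(raw))
    except (TypeError, ValueError):
        errors.append(f"line {line}: column {column!r} has non-numeric value {raw!r}")
        return 0
    if column != "degree" and value not in (0, 1):
        errors.append(f"line {line}: column {column!r} must be 0/1, got {value}")
    if column == "degree" and value < 0:
        errors.append(f"line {line}: column {column!r} must be >= 0, got {value}")
    return value


def read_dyad_records(
    path, dialect: Optional[Mapping[str, str]] = None, sep: str = ","
) -> list[DyadReport]:
    """Read a long-format dyadic report table from delimited text.

    Parameters
    ----------
    path
        Delimited text file with a header row.  Required canonical columns:
        ``family_id, informant_id, member_id, report, degree, same_gender,
        smokes, alcohol, healthy_weight, informant_female, informant_obese``.
    dialect
        Optional mapping from canonical column names to the names actually
        used in the file.
    sep
        Field separator.

    Missing reports (empty field or ``NA``) are retained with
    ``status=None``, never dropped silently.  Malformed rows are collected
    and reported with their line numbers in a single :class:`FormatError`.
    """
    dialect = dict(dialect or {})
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    rename = {dialect.get(col, col): col for col in COLUMN_TO_FIELD}
    frame = frame.rename(columns=rename)
    missing_cols = [c for c in COLUMN_TO_FIELD if c not in frame.columns]
    if missing_cols:
        raise FormatError(
            f"missing required column(s): {', '.join(sorted(missing_cols))}"
        )

    records: list[DyadReport] = []
    errors: list[str] = []
    for pos, row in enumerate(frame.itertuples(index=False)):
        line = pos + 2  # header is line 1
        raw = dict(zip(frame.columns, row))
        status_raw = str(raw["report"]).strip()
        if status_raw in ("", "NA", "NaN", "nan", "na", "."):
            status: Optional[int] = None
        else:
            status = _parse_binary(status_raw, "report", line, errors)
            if status not in (0, 1):
                errors.append(f"line {line}: report must be 0, 1 or NA, got {status_raw!r}")
        kwargs = {"status": status}
        for col in ("family_id", "informant_id", "member_id"):
            kwargs[col] = str(raw[col]).strip()
        for col, attr in COLUMN_TO_FIELD.items():
            if col in ("family_id", "informant_id", "member_id", "report"):
                continue
            kwargs[attr] = _parse_binary(raw[col], col, line, errors)
        records.append(DyadReport(**kwargs))

    if errors:
        raise FormatError("malformed rows:\n" + "\n".join(errors))
    validate_records(records)
    return records


def write_dyad_records(records: Iterable[DyadReport], path, sep: str = ",") -> None:
    """Write records as the canonical delimited table (missing status as ``NA``)."""
    rows = []
    for rec in records:
        row = {FIELD_TO_COLUMN[f.name]: getattr(rec, f.name) for f in dataclass_fields(rec)}
        row["report"] = "NA" if rec.status is None else rec.status
        rows.append(row)
    pd.DataFrame(rows, columns=list(COLUMN_TO_FIELD)).to_csv(path, sep=sep, index=False)


def validate_records(records: Sequence[DyadReport]) -> None:
    """Enforce the dataset-level invariants.

    Each (informant, member) pair must be unique, every id must belong to a
    single family, and each record must pass its own field checks.
    """
    seen: set[tuple[str, str]] = set()
    person_family: dict[str, str] = {}
    for rec in records:
        rec.validate()
        key = (rec.informant_id, rec.member_id)
        if key in seen:
            raise ValidationError(
                f"duplicate (informant, member) pair: {key[0]!r}, {key[1]!r}"
            )
        seen.add(key)
        for person in (rec.informant_id, rec.member_id):
            known = person_family.setdefault(person, rec.family_id)
            if known != rec.family_id:
                raise ValidationError(
                    f"id {person!r} appears in families {known!r} and {rec.family_id!r}; "
                    "informant and member must belong to the same family"
                )


def build_design(records: Sequence[DyadReport], spec: ModelSpec) -> DesignMatrices:
    """Assemble the response vector and design matrices for one model.

    Rows with a missing status are excluded from the likelihood (and counted
    in ``n_missing_excluded``); the remaining rows are sorted canonically by
    (family_id, member_id, informant_id).  ``X = [1 | level-1 covariates]``
    and ``W = [1 | level-2 covariates]`` in the order listed by ``spec``;
    ``g`` codes clusters 0..C-1 by first appearance in the sorted order.
    """
    validate_records(records)
    kept = [r for r in records if r.status is not None]
    n_missing = len(records) - len(kept)
    if not kept:
        raise DegenerateInputError("no records with an observed 0/1 status")
    kept.sort(key=lambda r: (r.family_id, r.member_id, r.informant_id))

    y = np.array([r.status for r in kept], dtype=float)
    X = np.column_stack(
        [np.ones(len(kept))]
        + [np.array([getattr(r, c) for r in kept], float) for c in spec.level1_covariates]
    )

    dyad_index = pd.DataFrame(
        {
            "family_id": [r.family_id for r in kept],
            "informant_id": [r.informant_id for r in kept],
            "member_id": [r.member_id for r in kept],
        }
    )
    n_informants = dyad_index["informant_id"].nunique()
    n_members = dyad_index["member_id"].nunique()

    if spec.cluster_level == "none":
        W = None
        g = None
        n_clusters = 0
    else:
        W = np.column_stack(
            [np.ones(len(kept))]
            + [np.array([getattr(r, c) for r in kept], float) for c in spec.level2_covariates]
        )
        key = "informant_id" if spec.cluster_level == "informant" else "family_id"
        labels = dyad_index[key].tolist()
        code_of: dict[str, int] = {}
        g = np.empty(len(labels), dtype=np.intp)
        for i, label in enumerate(labels):
            g[i] = code_of.setdefault(label, len(code_of))
        n_clusters = len(code_of)

    return DesignMatrices(
        y=y,
        X=X,
        W=W,
        g=g,
        dyad_index=dyad_index,
        spec=spec,
        n_clusters=n_clusters,
        n_informants=n_informants,
        n_members=n_members,
        n_missing_excluded=n_missing,
    )
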