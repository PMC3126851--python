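"""Cohort data model: Ct matrices, sample metadata, and ΔCt normalization.

qPCR expression is recorded as threshold-cycle (Ct) values: the PCR cycle at
which the fluorescence of an assay crosses a fixed threshold.  Lower Ct means
more template, i.e. higher expression.  Expression is normalized against an
endogenous small-RNA control (RNU48 on TaqMan miRNA panels):

    ΔCt = Ct(miRNA) − Ct(control),    relative expression = 2^(−ΔCt)

Reactions that never cross threshold within ``max_cycles`` cycles (commonly
40) are *undetected*; instruments export them as "Undetermined" or blank.
Undetected reactions are censored at the detection limit, not missing at
random, which is why downstream rank tests tolerate imputation at the bound.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CONTROL_ID = "RNU48"
DEFAULT_MAX_CYCLES = 40.0

#: cell encodings that mean "reaction never crossed threshold"
UNDETECTED_TOKENS = {"", "undetermined", "undet", "na", "nan", ">40"}

GROUPS = ("case", "control")
SETS = ("learning", "testing")
METADATA_COLUMNS = ["group", "set", "platform", "age", "sex", "education", "smoking"]
CONFOUNDERS = ["age", "sex", "education", "smoking"]


class CohortError(ValueError):
    """Raised for malformed or degenerate cohort inputs."""


@dataclass
class CtMatrix:
    """Raw threshold-cycle values for a panel of miRNA assays.

    Parameters
    ----------
    mirna_ids : list of str
        Assay names, one per row; must include ``control_id``.
    sample_ids : list of str
        Sample names, one per column.
    ct : ndarray of shape (n_mirna, n_samples)
        Cycle numbers.  For undetected cells the stored value is whatever the
        instrument reported (possibly NaN); ``detected`` is authoritative.
    detected : ndarray of bool, same shape
        False where the reaction never crossed threshold within
        ``max_cycles`` cycles.
    control_id : str
        Name of the endogenous-control assay used for ΔCt normalization.
    max_cycles : float
        Detection limit of the instrument in cycles.
    """

    mirna_ids: list[str]
    sample_ids: list[str]
    ct: np.ndarray
    detected: np.ndarray
    control_id: str = DEFAULT_CONTROL_ID
    max_cycles: float = DEFAULT_MAX_CYCLES

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.ct.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise CohortError(
                f"ct shape {self.ct.shape} does not match "
                f"{len(self.mirna_ids)} assays x {len(self.sample_ids)} samples"
            )
        if self.detected.shape != self.ct.shape:
            raise CohortError("detected and ct must have identical shape")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            dupes = sorted({m for m in self.mirna_ids if self.mirna_ids.count(m) > 1})
            raise CohortError(f"duplicate assay names: {dupes}")
        if self.control_id not in self.mirna_ids:
            raise CohortError(f"control assay not found: {self.control_id!r}")
        with np.errstate(invalid="ignore"):
            over = self.detected & (self.ct > self.max_cycles)
        if over.any():
            raise CohortError("detected Ct values above max_cycles")

    @property
    def control_index(self) -> int:
        return self.mirna_ids.index(self.control_id)

    def assay_index(self, mirna_id: str) -> int:
        return self.mirna_ids.index(mirna_id)

    def select_samples(self, sample_ids: list[str]) -> "CtMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CtMatrix(
            mirna_ids=list(self.mirna_ids),
            sample_ids=list(sample_ids),
            ct=self.ct[:, idx],
            detected=self.detected[:, idx],
            control_id=self.control_id,
            max_cycles=self.max_cycles,
        )

    def to_frame(self) -> pd.DataFrame:
        """Render as a table of strings suitable for TSV/CSV export.

        Detected cells carry their Ct value.  Undetected cells with a
        recorded cycle number beyond ``max_cycles`` keep it (it reads back
        as undetected by the censoring rule); undetected cells without a
        representable value become "Undetermined".
        """
        with np.errstate(invalid="ignore"):
            numeric = self.detected | (np.isfinite(self.ct) & (self.ct > self.max_cycles))
        cells = np.where(numeric, np.char.mod("%.17g", self.ct), "Undetermined")
        return pd.DataFrame(cells, index=self.mirna_ids, columns=self.sample_ids)


@dataclass
class ExpressionMatrix:
    """Normalized expression: ΔCt, relative expression 2^(−ΔCt).

    The control row is removed during normalization.  ``imputed`` marks cells
    whose ΔCt was filled in at the detection limit because the reaction was
    undetected (censored), as opposed to measured.
    """

    mirna_ids: list[str]
    sample_ids: list[str]
    delta_ct: np.ndarray
    rel_expr: np.ndarray = field(default=None)  # type: ignore[assignment]
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.delta_ct = np.asarray(self.delta_ct, dtype=float)
        if self.rel_expr is None:
            self.rel_expr = np.exp2(-self.delta_ct)
        self.rel_expr = np.asarray(self.rel_expr, dtype=float)
        if self.imputed is None:
            self.imputed = np.zeros_like(self.delta_ct, dtype=bool)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        shape = (len(self.mirna_ids), len(self.sample_ids))
        if self.delta_ct.shape != shape:
            raise CohortError(f"delta_ct shape {self.delta_ct.shape} != {shape}")

    @property
    def minus_delta_ct(self) -> np.ndarray:
        """−ΔCt, the expression-level scale (higher = more expressed)."""
        return -self.delta_ct

    def assay_index(self, mirna_id: str) -> int:
        return self.mirna_ids.index(mirna_id)

    def subset(self, mirna_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.assay_index(m) for m in mirna_ids]
        return ExpressionMatrix(
            mirna_ids=list(mirna_ids),
            sample_ids=list(self.sample_ids),
            delta_ct=self.delta_ct[idx],
            rel_expr=self.rel_expr[idx],
            imputed=self.imputed[idx],
        )

    def select_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            mirna_ids=list(self.mirna_ids),
            sample_ids=list(sample_ids),
            delta_ct=self.delta_ct[:, idx],
            rel_expr=self.rel_expr[:, idx],
            imputed=self.imputed[:, idx],
        )

    def to_frame(self, scale: str = "delta_ct") -> pd.DataFrame:
        mat = {
            "delta_ct": self.delta_ct,
            "minus_delta_ct": -self.delta_ct,
            "rel_expr": self.rel_expr,
        }[scale]
        return pd.DataFrame(mat, index=self.mirna_ids, columns=self.sample_ids)


class SampleTable:
    """Sample metadata: group, analysis set, platform, and confounders.

    Thin wrapper over a DataFrame indexed by sample id with columns
    group / set / platform / age / sex / education / smoking.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.has_duplicates:
            raise CohortError("duplicate sample ids in metadata")
        missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
        if missing:
            raise CohortError(f"metadata missing columns: {missing}")
        bad_groups = set(frame["group"]) - set(GROUPS)
        if bad_groups:
            raise CohortError(f"unknown group labels: {sorted(bad_groups)}")
        bad_sets = set(frame["set"]) - set(SETS)
        if bad_sets:
            raise CohortError(f"unknown set labels: {sorted(bad_sets)}")
        for s in sorted(set(frame["set"])):
            sub = frame[frame["set"] == s]
            if not all((sub["group"] == g).any() for g in GROUPS):
                raise CohortError(f"set {s!r} lacks one of the groups {GROUPS}")
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, analysis_set: str) -> "SampleTable":
        sub = self.frame[self.frame["set"] == analysis_set]
        if sub.empty:
            raise CohortError(f"no samples in set {analysis_set!r}")
        return SampleTable(sub)

    def labels(self, sample_ids: list[str] | None = None) -> np.ndarray:
        """Binary outcome vector: case=1, control=0."""
        col = self.frame["group"]
        if sample_ids is not None:
            col = col.loc[sample_ids]
        return (col == "case").to_numpy(dtype=int)

    def confounder_matrix(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        """Numeric design for the confounders age/sex/education/smoking."""
        sub = self.frame if sample_ids is None else self.frame.loc[sample_ids]
        out = pd.DataFrame(index=sub.index)
        out["age"] = pd.to_numeric(sub["age"])
        out["sex"] = sub["sex"].map({"M": 1.0, "F": 0.0, 1: 1.0, 0: 0.0})
        out["education"] = pd.to_numeric(sub["education"])
        out["smoking"] = sub["smoking"].map({"yes": 1.0, "no": 0.0, 1: 1.0, 0: 0.0})
        bad = out.columns[out.isna().any()].tolist()
        if bad:
            rows = out.index[out[bad].isna().any(axis=1)].tolist()
            raise CohortError(f"missing confounder values {bad} for samples {rows}")
        return out

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleTable) and self.frame.equals(other.frame)


# ---------------------------------------------------------------------------
# I/O


def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_ct_table(
    path,
    control_id: str = DEFAULT_CONTROL_ID,
    max_cycles: float = DEFAULT_MAX_CYCLES,
) -> CtMatrix:
    """Read a Ct table (rows = assays, columns = samples) from TSV/CSV.

    Undetected reactions may be encoded as an empty cell, "Undetermined"
    (case-insensitive, as TaqMan software exports), "NA", ">40", or a numeric
    value above ``max_cycles``; all are flagged detected=False.  Numeric
    values are preserved losslessly where present.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                      keep_default_na=False)
    mirna_ids = [str(i) for i in raw.index]
    sample_ids = [str(c) for c in raw.columns]
    ct = np.full(raw.shape, np.nan)
    detected = np.zeros(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw.iat[i, j]).strip()
            if cell.lower() in UNDETECTED_TOKENS or cell.startswith(">"):
                continue
            value = float(cell)
            ct[i, j] = value
            detected[i, j] = value <= max_cycles
    if control_id not in mirna_ids:
        raise CohortError(f"control assay not found: {control_id!r}")
    return CtMatrix(mirna_ids, sample_ids, ct, detected,
                    control_id=control_id, max_cycles=max_cycles)


def write_ct_table(ct: CtMatrix, path) -> None:
    ct.to_frame().to_csv(path, sep=_sep_for(path), index_label="mirna_id")


def read_sample_table(path) -> SampleTable:
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    frame.index = frame.index.astype(str)
    return SampleTable(frame)


def write_sample_table(samples: SampleTable, path) -> None:
    samples.frame.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_clinical_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    frame.index = frame.index.astype(str)
    return frame


# ---------------------------------------------------------------------------
# Normalization


def normalize_delta_ct(ct: CtMatrix, impute_censored: bool = True) -> ExpressionMatrix:
    """Normalize Ct to ΔCt against the endogenous control.

    ΔCt[i, s] = Ct[i, s] − Ct[control, s] for detected cells.  Undetected
    (censored) cells are either imputed at the detection limit,
    ΔCt = max_cycles − Ct(control, s), and flagged in ``imputed``
    (default), or left missing (NaN) when ``impute_censored`` is False.
    Relative expression is 2^(−ΔCt).

    Raises
    ------
    CohortError
        If the control assay is undetected in any sample (normalization is
        then undefined for that sample); the error lists the samples.
    """
    ctrl = ct.control_index
    undet_ctrl = ~ct.detected[ctrl]
    if undet_ctrl.any():
        bad = [s for s, u in zip(ct.sample_ids, undet_ctrl) if u]
        raise CohortError(f"control {ct.control_id!r} undetected in samples: {bad}")
    control_ct = ct.ct[ctrl]

    keep = [i for i in range(len(ct.mirna_ids)) if i != ctrl]
    values = ct.ct[keep]
    detected = ct.detected[keep]
    delta = values - control_ct[None, :]
    imputed = np.zeros_like(detected)
    if impute_censored:
        limit = ct.max_cycles - control_ct[None, :]
        delta = np.where(detected, delta, np.broadcast_to(limit, delta.shape))
        imputed = ~detected
    else:
        delta = np.where(detected, delta, np.nan)
    return ExpressionMatrix(
        mirna_ids=[ct.mirna_ids[i] for i in keep],
        sample_ids=list(ct.sample_ids),
        delta_ct=delta,
        imputed=imputed,
    )
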