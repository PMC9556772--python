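"""Screen preprocessing: I/O, filtering, kNN imputation and IC50* scores.

The pipeline order is: align samples, filter biomarkers and drugs, impute
missing IC50s, then normalize to IC50*.  IC50* is a per-drug centered
log10(IC50) shifted so the per-drug maximum is exactly 0; it emphasises the
*differential* (genotype-dependent) effect of a drug over its absolute
potency, so that uniformly toxic drugs contribute ~0 to the downstream
tree objective while differential drugs retain large negative scores.
"""

from __future__ import annotations

import logging
import os
import warnings

import numpy as np
import pandas as pd

from .containers import LesionMatrix, NormalizedMatrix, ResponseMatrix

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "read_lesion_matrix",
    "write_lesion_matrix",
    "read_drug_targets",
    "align_samples",
    "filter_biomarkers",
    "filter_drugs",
    "knn_impute",
    "normalize_ic50_star",
    "write_normalized_matrix",
    "IC50_MAX_UM",
]

logger = logging.getLogger(__name__)

#: upper end of the assay's reportable concentration range, µM
IC50_MAX_UM = 10.0


def _sep_for(path: str) -> str:
    return "," if os.fspath(path).endswith(".csv") else "\t"


def _read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)


# ---------------------------------------------------------------------------
# I/O


def read_response_matrix(path: str, clip_high: bool = False) -> ResponseMatrix:
    """Read a drugs x patients IC50 matrix (CSV/TSV; empty cell = missing).

    Values must be positive µM concentrations.  Values above 10 µM are
    clipped to 10 with a logged warning when ``clip_high`` is set and
    rejected otherwise.
    """
    raw = _read_table(path)
    if raw.index.has_duplicates or raw.columns.has_duplicates:
        raise ValueError(f"duplicate drug or patient identifiers in {path}")
    df = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str),
                      dtype=float)
    for col in raw.columns:
        for row in raw.index:
            cell = raw.at[row, col]
            if pd.isna(cell) or (isinstance(cell, str) and not cell.strip()):
                continue
            try:
                df.at[str(row), str(col)] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"malformed numeric cell at drug {row!r}, patient {col!r}: "
                    f"{cell!r}"
                ) from exc
    vals = df.to_numpy()
    over = np.isfinite(vals) & (vals > IC50_MAX_UM)
    if over.any():
        if not clip_high:
            raise ValueError(
                f"{int(over.sum())} IC50 values exceed {IC50_MAX_UM} µM; "
                "pass clip_high=True to clip them"
            )
        logger.warning(
            "clipping %d IC50 values above %.1f µM", int(over.sum()), IC50_MAX_UM
        )
        df = df.clip(upper=IC50_MAX_UM)
    return ResponseMatrix(df)


def write_response_matrix(resp: ResponseMatrix, path: str) -> None:
    resp.values.to_csv(path, sep=_sep_for(path), na_rep="")


def read_lesion_matrix(
    path: str,
    format: str = "matrix",
    roster: list[str] | None = None,
) -> LesionMatrix:
    """Read a binary lesion matrix.

    Parameters
    ----------
    format
        ``"matrix"`` — lesions x patients 0/1 table; ``"long_table"`` —
        two-column (patient_id, lesion_id) table, one row per event;
        ``"maf"`` — Mutation Annotation Format, binarized to gene level
        (any row for a (gene, sample) pair sets the cell to 1).
    roster
        Optional full patient list; patients without any event still get a
        zero column.  Only consulted for ``long_table`` and ``maf``.
    """
    if format == "matrix":
        df = _read_table(path)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("matrix-format lesion file must contain only 0/1 cells")
        return LesionMatrix(df.astype(np.int8))
    if format == "long_table":
        tab = pd.read_csv(path, sep=_sep_for(path))
        pairs = list(zip(tab.iloc[:, 0].astype(str), tab.iloc[:, 1].astype(str)))
    elif format == "maf":
        tab = pd.read_csv(path, sep="\t", comment="#")
        cols = {c.lower(): c for c in tab.columns}
        try:
            gene_col = cols["hugo_symbol"]
            samp_col = cols["tumor_sample_barcode"]
        except KeyError as exc:
            raise ValueError(
                "MAF file must carry Hugo_Symbol and Tumor_Sample_Barcode columns"
            ) from exc
        pairs = list(zip(tab[samp_col].astype(str), tab[gene_col].astype(str)))
    else:
        raise ValueError(f"unknown lesion format {format!r}")

    patients = sorted({p for p, _ in pairs} | set(map(str, roster or [])))
    lesions = sorted({l for _, l in pairs})
    status = pd.DataFrame(0, index=lesions, columns=patients, dtype=np.int8)
    for p, l in pairs:
        status.at[l, p] = 1
    return LesionMatrix(status)


def write_lesion_matrix(lesions: LesionMatrix, path: str) -> None:
    lesions.status.to_csv(path, sep=_sep_for(path))


def read_drug_targets(path: str) -> dict[str, str]:
    """Read a two-column (drug_id, gene_id) TSV/CSV mapping."""
    tab = pd.read_csv(path, sep=_sep_for(path))
    return dict(zip(tab.iloc[:, 0].astype(str), tab.iloc[:, 1].astype(str)))


def write_normalized_matrix(norm: NormalizedMatrix, path: str) -> None:
    norm.values.to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# Filtering and alignment


def align_samples(
    resp: ResponseMatrix, lesions: LesionMatrix
) -> tuple[ResponseMatrix, LesionMatrix]:
    """Restrict both matrices to their shared patients, in a common order."""
    common = [p for p in resp.patient_ids if p in set(lesions.patient_ids)]
    if not common:
        raise ValueError("response and lesion matrices share no patients")
    return (
        ResponseMatrix(resp.values.loc[:, common]),
        LesionMatrix(lesions.status.loc[:, common]),
    )


def filter_biomarkers(
    lesions: LesionMatrix, min_fraction: float = 0.01
) -> LesionMatrix:
    """Keep lesions carried by strictly more than ``min_fraction`` of patients.

    The strict inequality reproduces the "more than 1% of patients" rule:
    at P=319 a lesion needs at least 4 carriers (3.19 < 4).
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    threshold = min_fraction * lesions.n_patients
    keep = lesions.prevalence > threshold
    if not keep.any():
        warnings.warn("biomarker prevalence filter removed every lesion")
    return LesionMatrix(lesions.status.loc[keep[keep].index])


def filter_drugs(
    resp: ResponseMatrix,
    min_tested_fraction: float = 0.20,
    targets: dict[str, str] | None = None,
) -> ResponseMatrix:
    """Drop sparsely tested drugs, and drugs without an annotated target.

    A drug is kept when its non-missing fraction is >= ``min_tested_fraction``
    and — if a drug→target-gene mapping is supplied — it appears in that
    mapping.  Without a mapping the target filter is skipped.
    """
    if not 0 <= min_tested_fraction <= 1:
        raise ValueError("min_tested_fraction must be in [0, 1]")
    tested = resp.values.notna().mean(axis=1)
    keep = tested >= min_tested_fraction
    if targets is not None:
        keep &= resp.values.index.to_series().isin(targets)
    if not keep.any():
        raise ValueError("drug filters removed every drug")
    return ResponseMatrix(resp.values.loc[keep[keep].index])


# ---------------------------------------------------------------------------
# Imputation


def knn_impute(resp: ResponseMatrix, k: int = 10) -> ResponseMatrix:
    """Fill missing IC50s by k-nearest-neighbour drug rows on log10 scale.

    For a missing (drug t, patient p) the k nearest drug rows — Euclidean
    distance over columns observed in both rows, scaled by the shared-column
    count so rows with different overlap compare fairly — are averaged at
    column p.  Neighbours themselves missing at p are skipped; if none is
    usable the drug's own row mean fills in.  Imputation operates on log10
    values; the result is back-transformed to µM.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = np.log10(resp.values.to_numpy(dtype=float))
    obs = np.isfinite(vals)
    if obs.all():
        return resp.copy()
    fully_missing = ~obs.any(axis=1)
    if fully_missing.any():
        bad = [resp.drug_ids[i] for i in np.where(fully_missing)[0]]
        raise ValueError(
            f"drug rows fully missing ({bad}); run filter_drugs first"
        )
    T = vals.shape[0]
    out = vals.copy()
    row_means = np.array([vals[t, obs[t]].mean() for t in range(T)])
    for t in np.where(~obs.all(axis=1))[0]:
        # scaled distance to every other drug row
        dist = np.full(T, np.inf)
        for s in range(T):
            if s == t:
                continue
            shared = obs[t] & obs[s]
            n = int(shared.sum())
            if n == 0:
                continue
            diff = vals[t, shared] - vals[s, shared]
            dist[s] = np.sqrt((diff**2).sum() / n)
        order = np.argsort(dist, kind="stable")
        neighbors = [s for s in order if np.isfinite(dist[s])][:k]
        for p in np.where(~obs[t])[0]:
            usable = [s for s in neighbors if obs[s, p]]
            out[t, p] = np.mean(vals[usable, p]) if usable else row_means[t]
    filled = pd.DataFrame(
        np.power(10.0, out), index=resp.values.index, columns=resp.values.columns
    )
    return ResponseMatrix(filled)


# ---------------------------------------------------------------------------
# Normalization


def normalize_ic50_star(resp: ResponseMatrix) -> NormalizedMatrix:
    """Transform a complete IC50 matrix (µM) into IC50* scores.

    Per drug row t:  ``c_{t,p} = (log10(ic50_{t,p}) - 1) - mean_p(...)``,
    then ``ic50*_{t,p} = c_{t,p} - max_p(c_{t,p})``.  The "- 1" is inert —
    it cancels under centering — but is kept so the computed score matches
    the published transformation verbatim.  Every row ends with maximum
    exactly 0 and all values <= 0; multiplying a row's raw IC50s by any
    positive constant leaves its IC50* unchanged.
    """
    vals = resp.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("IC50 matrix has missing values; run knn_impute first")
    shifted = np.log10(vals) - 1.0
    centered = shifted - shifted.mean(axis=1, keepdims=True)
    star = centered - centered.max(axis=1, keepdims=True)
    star = np.minimum(star, 0.0)  # clamp +0.0 round-off on the argmax cell
    return NormalizedMatrix(
        pd.DataFrame(star, index=resp.values.index, columns=resp.values.columns)
    )
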