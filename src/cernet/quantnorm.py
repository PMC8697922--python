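"""Abundance normalizations (FPKM, TPM, RPM) and 2^-ddCt relative quantitation.

Each RNA layer carries its own per-million convention: FPKM for
mRNA/lncRNA (length-corrected), TPM for miRNA clean tags, and RPM for
circRNA back-spliced junction reads.  RT-qPCR validation data is
summarized with the 2^-ddCt method against housekeeping references.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from cernet.matrix import ExpressionMatrix

__all__ = [
    "fpkm",
    "fpkm_matrix",
    "tpm_mirna",
    "tpm_matrix",
    "rpm_circ",
    "rpm_matrix",
    "ddct",
]


def fpkm(counts, lengths, total_fragments: float):
    """Fragments per kilobase of transcript per million mapped fragments.

    value = 1e9 * count / (length_bp * total_fragments); vectorized over
    ``counts``/``lengths``.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("feature lengths must be positive (bp)")
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    return 1e9 * counts / (lengths * total_fragments)


def tpm_mirna(count, total_clean_tags: float, literal_formula: bool = False):
    """Tags per million for miRNA clean-tag counts.

    By default value = 1e6 * count / total_clean_tags (per-million
    semantics).  ``literal_formula=True`` instead evaluates
    count / (total_clean_tags * 1e6), a compatibility mode for the
    as-printed variant of the formula whose units disagree with the
    per-million name by a factor of 1e12.
    """
    count = np.asarray(count, dtype=float)
    if total_clean_tags <= 0:
        raise ValueError("total_clean_tags must be positive")
    if np.any(count < 0):
        raise ValueError("counts must be nonnegative")
    if literal_formula:
        return count / (total_clean_tags * 1e6)
    return 1e6 * count / total_clean_tags


def rpm_circ(c, n: float):
    """Back-spliced reads per million: RPM = 1e6 * C / N.

    C is the junction-read count assigned to one circRNA, N the total
    back-spliced junction reads of the library.
    """
    c = np.asarray(c, dtype=float)
    if n <= 0:
        raise ValueError("total back-spliced junction reads must be positive")
    if np.any(c < 0):
        raise ValueError("junction read counts must be nonnegative")
    if np.any(c > n):
        raise ValueError("per-circRNA junction reads cannot exceed the library total")
    return 1e6 * c / n


# -- matrix-level wrappers used by the pipeline --------------------------------


def fpkm_matrix(matrix: ExpressionMatrix, lengths: pd.Series | None = None) -> ExpressionMatrix:
    """FPKM-normalize a counts matrix column by column.

    Per-sample total fragments are the column sums; lengths come from the
    argument or from ``matrix.feature_lengths``.
    """
    _require_counts(matrix)
    if lengths is None:
        lengths = matrix.feature_lengths
    if lengths is None:
        raise ValueError("feature lengths required for FPKM")
    lengths = lengths.loc[matrix.values.index]
    totals = matrix.library_sizes()
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive library size")
    out = pd.DataFrame(
        {s: fpkm(matrix.values[s].to_numpy(), lengths.to_numpy(), totals[s]) for s in matrix.sample_ids},
        index=matrix.values.index,
    )
    return ExpressionMatrix(matrix.layer, out, matrix.conditions, scale="FPKM", feature_lengths=lengths)


def tpm_matrix(matrix: ExpressionMatrix) -> ExpressionMatrix:
    _require_counts(matrix)
    totals = matrix.library_sizes()
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive library size")
    out = matrix.values / totals * 1e6
    return ExpressionMatrix(matrix.layer, out, matrix.conditions, scale="TPM")


def rpm_matrix(matrix: ExpressionMatrix, totals: pd.Series | None = None) -> ExpressionMatrix:
    """RPM-normalize junction counts; totals default to column sums."""
    _require_counts(matrix)
    if totals is None:
        totals = matrix.library_sizes()
    totals = pd.Series(totals).loc[matrix.sample_ids]
    out = pd.DataFrame(
        {s: rpm_circ(matrix.values[s].to_numpy(), totals[s]) for s in matrix.sample_ids},
        index=matrix.values.index,
    )
    return ExpressionMatrix(matrix.layer, out, matrix.conditions, scale="RPM")


def _require_counts(matrix: ExpressionMatrix) -> None:
    if matrix.scale != "counts":
        raise ValueError(f"expected a counts matrix, got scale={matrix.scale!r}")


# -- RT-qPCR -------------------------------------------------------------------


def ddct(
    records: pd.DataFrame,
    target: str,
    test_condition: str = "GF_T",
    calibrator_condition: str = "GF_C",
    replicate_sd_limit: float = 0.5,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ``records`` needs columns (sample, condition, gene, role, ct) with
    role in {target, reference}.  Per condition, dCt = mean target Ct -
    mean reference Ct (multiple housekeeping genes are averaged
    arithmetically); ddCt = dCt(test) - dCt(calibrator); the return value
    is 2**-ddCt.  Replicate groups whose Ct standard deviation exceeds
    ``replicate_sd_limit`` cycles are flagged with a warning.
    """
    required = {"sample", "condition", "gene", "role", "ct"}
    if not required.issubset(records.columns):
        raise ValueError(f"qPCR table must have columns {sorted(required)}")
    if not np.isfinite(records["ct"].to_numpy(dtype=float)).all():
        raise ValueError("Ct values must be finite")

    dct = {}
    for cond in (test_condition, calibrator_condition):
        sub = records[records["condition"] == cond]
        tgt = sub[(sub["gene"] == target) & (sub["role"] == "target")]["ct"]
        ref = sub[sub["role"] == "reference"]["ct"]
        if tgt.empty:
            raise ValueError(f"no target Ct values for {target!r} in condition {cond!r}")
        if ref.empty:
            raise ValueError(f"no reference-gene Ct values in condition {cond!r}")
        for gene, grp in sub.groupby("gene"):
            if len(grp) >= 2 and grp["ct"].std(ddof=1) > replicate_sd_limit:
                warnings.warn(
                    f"replicate Ct SD for {gene!r} in {cond!r} exceeds "
                    f"{replicate_sd_limit} cycles",
                    stacklevel=2,
                )
        dct[cond] = tgt.mean() - ref.mean()

    ddct_value = dct[test_condition] - dct[calibrator_condition]
    return float(2.0 ** (-ddct_value))
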