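"""Back-splice junction candidate filtering and RPM quantification.

A circRNA candidate is kept only if all seven criteria hold:

a. exactly one clear breakpoint;
b. anchor-alignment overlap at most 2 bp;
c. at most 2 bp of edit distance (mismatches);
d. more than 2 unique junction reads;
e. the best anchor mapping beats the runner-up by a score above 35 on
   at least one side;
f. unique junction reads exceed ``int(n_samples / 2)`` (integer floor);
g. genomic span below 100 kb.

Coordinates follow the BED convention (0-based, half-open); the span is
``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cernet.matrix import ExpressionMatrix
from cernet.quantnorm import rpm_circ

__all__ = [
    "CircCandidate",
    "CRITERIA",
    "MAX_CIRC_LENGTH",
    "apply_filters",
    "candidates_to_frame",
    "quantify_rpm",
    "write_bed",
    "read_candidates_tsv",
    "write_candidates_tsv",
]

CRITERIA = ("a", "b", "c", "d", "e", "f", "g")
MAX_CIRC_LENGTH = 100_000


@dataclass
class CircCandidate:
    """One back-splice junction candidate with its filter statistics."""

    candidate_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    breakpoint_count: int
    anchor_overlap: int
    edit_distance: int
    n_uniq: int
    best_qual_A: int
    best_qual_B: int
    per_sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"candidate {self.candidate_id}: end must exceed start")
        for name in ("breakpoint_count", "anchor_overlap", "edit_distance", "n_uniq"):
            if getattr(self, name) < 0:
                raise ValueError(f"candidate {self.candidate_id}: negative {name}")
        if any(v < 0 for v in self.per_sample_counts.values()):
            raise ValueError(f"candidate {self.candidate_id}: negative per-sample count")


def apply_filters(
    candidates: list[CircCandidate] | pd.DataFrame, n_samples: int
) -> pd.DataFrame:
    """Per-criterion and overall verdicts for each candidate.

    Returns a DataFrame indexed by candidate_id with boolean columns
    a..g and ``overall`` (the conjunction).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    if isinstance(candidates, pd.DataFrame):
        df = candidates
    else:
        for cand in candidates:
            cand.validate()
        df = candidates_to_frame(candidates)
    if len(df):
        if (df["end"] <= df["start"]).any():
            bad = df.loc[df["end"] <= df["start"], "candidate_id"].iloc[0]
            raise ValueError(f"candidate {bad}: end must exceed start")
        count_cols = ["breakpoint_count", "anchor_overlap", "edit_distance", "n_uniq"]
        neg = (df[count_cols] < 0).any(axis=1)
        if neg.any():
            raise ValueError(
                f"candidate {df.loc[neg, 'candidate_id'].iloc[0]}: negative count field"
            )

    length = df["end"] - df["start"]
    verdict = pd.DataFrame(
        {
            "a": df["breakpoint_count"] == 1,
            "b": df["anchor_overlap"] <= 2,
            "c": df["edit_distance"] <= 2,
            "d": df["n_uniq"] > 2,
            "e": (df["best_qual_A"] > 35) | (df["best_qual_B"] > 35),
            "f": df["n_uniq"] > int(n_samples / 2),
            "g": length < MAX_CIRC_LENGTH,
        }
    )
    verdict["overall"] = verdict[list(CRITERIA)].all(axis=1)
    verdict.index = pd.Index(df["candidate_id"], name="candidate_id")
    return verdict


def candidates_to_frame(candidates: list[CircCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {
            "candidate_id": c.candidate_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "breakpoint_count": c.breakpoint_count,
            "anchor_overlap": c.anchor_overlap,
            "edit_distance": c.edit_distance,
            "n_uniq": c.n_uniq,
            "best_qual_A": c.best_qual_A,
            "best_qual_B": c.best_qual_B,
        }
        for s, v in c.per_sample_counts.items():
            row[f"count_{s}"] = v
        rows.append(row)
    cols = [
        "candidate_id", "chrom", "start", "end", "strand", "breakpoint_count",
        "anchor_overlap", "edit_distance", "n_uniq", "best_qual_A", "best_qual_B",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def quantify_rpm(
    candidates: pd.DataFrame,
    verdicts: pd.DataFrame,
    junction_totals: pd.Series,
    conditions: pd.Series,
) -> ExpressionMatrix:
    """RPM matrix over candidates passing every filter.

    ``candidates`` must carry ``count_<sample>`` columns;
    ``junction_totals`` are the per-sample total back-spliced junction
    reads.
    """
    junction_totals = pd.Series(junction_totals)
    if (junction_totals <= 0).any():
        raise ValueError("per-sample junction totals must all be positive")
    passing = verdicts.index[verdicts["overall"]]
    sub = candidates.set_index("candidate_id").loc[list(passing)]
    samples = list(junction_totals.index)
    data = {}
    for s in samples:
        col = f"count_{s}"
        if col not in sub.columns and len(sub):
            raise ValueError(f"candidate table lacks per-sample counts for {s!r}")
        counts = sub[col].to_numpy(dtype=float) if len(sub) else np.array([])
        data[s] = rpm_circ(counts, float(junction_totals[s]))
    values = pd.DataFrame(data, index=sub.index)
    return ExpressionMatrix("circRNA", values, conditions, scale="RPM")


# -- I/O -----------------------------------------------------------------------


def write_bed(candidates: pd.DataFrame, verdicts: pd.DataFrame, path: str | Path) -> None:
    """Passing candidates as BED6 (chrom, start, end, id, n_uniq, strand)."""
    passing = verdicts.index[verdicts["overall"]]
    sub = candidates.set_index("candidate_id").loc[list(passing)]
    bed = pd.DataFrame(
        {
            "chrom": sub["chrom"],
            "start": sub["start"],
            "end": sub["end"],
            "name": sub.index,
            "score": sub["n_uniq"],
            "strand": sub["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_candidates_tsv(candidates: pd.DataFrame, path: str | Path) -> None:
    candidates.to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
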