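"""Hypergeometric term enrichment against GMT annotation sets.

For each annotation term, the study set's overlap k out of n study
genes is scored against K annotated genes in a population of N with the
upper hypergeometric tail P(X >= k) (one-sided Fisher test), followed
by Benjamini-Hochberg correction across terms.  A term is significant
when its corrected p is strictly below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from cernet.diffexpr import bh_fdr

__all__ = ["AnnotationSet", "read_gmt", "write_gmt", "hypergeom_enrich"]

ENRICH_ALPHA = 0.05


@dataclass
class AnnotationSet:
    """One term with its member gene ids."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"term {self.term_id}: empty member set")


def read_gmt(path: str | Path) -> list[AnnotationSet]:
    terms = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        term_id, name, genes = fields[0], fields[1], fields[2:]
        if term_id in seen:
            raise ValueError(f"duplicate term id {term_id!r} in GMT")
        seen.add(term_id)
        terms.append(AnnotationSet(term_id, name, frozenset(g for g in genes if g)))
    return terms


def write_gmt(terms: list[AnnotationSet], path: str | Path) -> None:
    lines = [
        "\t".join([t.term_id, t.term_name, *sorted(t.members)]) for t in terms
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def hypergeom_enrich(
    study: set[str],
    population: set[str],
    annotation: list[AnnotationSet],
    alpha: float = ENRICH_ALPHA,
) -> pd.DataFrame:
    """Enrichment of ``study`` within ``population`` for each term.

    Returns one row per term with k (study hits), K (population hits),
    n (study size), N (population size), the raw upper-tail p, BH
    corrected p, and the significance call, sorted by corrected p.
    """
    study = set(study)
    population = set(population)
    if not population:
        raise ValueError("population must be nonempty")
    if not study:
        raise ValueError("study set must be nonempty")
    strays = study - population
    if strays:
        raise ValueError(f"study genes outside population: {sorted(strays)[:10]}")

    n_pop = len(population)
    n_study = len(study)
    rows = []
    for term in annotation:
        members = term.members & population
        k_pop = len(members)
        k_study = len(members & study)
        p = float(stats.hypergeom.sf(k_study - 1, n_pop, k_pop, n_study)) if k_pop else 1.0
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "k": k_study,
                "K": k_pop,
                "n": n_study,
                "N": n_pop,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"]
    )
    if len(out):
        out["corrected_p"] = bh_fdr(out["p_value"].to_numpy())
        out["significant"] = out["corrected_p"] < alpha
        out = out.sort_values(["corrected_p", "p_value", "term_id"]).reset_index(drop=True)
    else:
        out["corrected_p"] = []
        out["significant"] = []
    return out
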