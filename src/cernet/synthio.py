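"""Seeded synthetic multi-layer RNA data with planted ground truth.

The generator emulates the study design the pipeline targets: two
follicle-size conditions (GF_C large, GF_T small) with a small number
of pooled sample groups each, four RNA layers (mRNA, lncRNA, miRNA,
circRNA) of negative-binomial counts, planted differentially expressed
features, planted ceRNA triplets in which a miRNA is negatively
coupled to both an mRNA and a lncRNA/circRNA sponge through a shared
per-sample latent profile, back-splice circRNA candidate records with
known per-criterion verdicts, and three simulated miRNA-target
prediction sources with tunable sensitivity/specificity.

Randomness: one root seed feeds an explicit spawn-key substream per
output, so adding a new output never perturbs existing ones and equal
configs produce bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cernet.circfilter import CircCandidate
from cernet.enrich import AnnotationSet
from cernet.matrix import ExpressionMatrix, write_condition_map

__all__ = [
    "SynthConfig",
    "TruthTable",
    "generate_counts",
    "generate_circ_candidates",
    "generate_prediction_tables",
    "generate_annotation",
    "write_dataset",
]

LAYER_STREAMS = {"mRNA": 0, "lncRNA": 1, "miRNA": 2, "circRNA": 3}
TRIPLET_STREAM = 4
CIRC_STREAM = 5
PREDICTION_STREAMS = (6, 7, 8)
ANNOTATION_STREAM = 9

LOG2_MEAN_CAP = 16.0  # keep NB means (and exact-test totals) bounded

DEFAULT_N_FEATURES = {"mRNA": 2000, "lncRNA": 500, "miRNA": 300, "circRNA": 1000}
#: planted-DE prevalence per layer, matching the order of magnitude a
#: whole-transcriptome follicle comparison reports (a fraction of a
#: percent of mRNAs up to a few percent of miRNAs)
DEFAULT_FRAC_DE = {"mRNA": 0.005, "lncRNA": 0.008, "miRNA": 0.045, "circRNA": 0.021}


@dataclass
class SynthConfig:
    """Generator parameters; defaults define the simulated study conditions."""

    n_samples_per_condition: int = 3
    n_features: dict = field(default_factory=lambda: dict(DEFAULT_N_FEATURES))
    frac_de: dict | float = field(default_factory=lambda: dict(DEFAULT_FRAC_DE))
    log2fc_magnitude: float = 2.0
    nb_dispersion: float = 0.02
    de_profile_sd: float = 3.0
    n_triplets: int = 10
    triplet_log2fc: float = 3.5
    triplet_profile_sd: float = 3.0
    corr_noise_sd: float = 0.1
    pred_sensitivity: float = 0.9
    pred_specificity: float = 0.98
    n_circ_candidates: int = 500
    n_decoy_pairs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_condition < 2:
            raise ValueError("n_samples_per_condition must be >= 2")
        if isinstance(self.frac_de, (int, float)):
            self.frac_de = {layer: float(self.frac_de) for layer in LAYER_STREAMS}
        for layer in LAYER_STREAMS:
            if layer not in self.n_features:
                raise ValueError(f"n_features missing layer {layer!r}")
            if self.n_features[layer] < 0:
                raise ValueError(f"n_features[{layer!r}] must be >= 0")
            frac = self.frac_de.get(layer, 0.0)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"frac_de[{layer!r}] must lie in [0, 1]")
        for name in ("pred_sensitivity", "pred_specificity"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("nb_dispersion", "corr_noise_sd", "de_profile_sd", "triplet_profile_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("log2fc_magnitude", "triplet_log2fc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_triplets", "n_circ_candidates", "n_decoy_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        min_per_layer = {"miRNA": self.n_triplets, "mRNA": self.n_triplets}
        min_per_layer["circRNA"] = (self.n_triplets + 1) // 2
        min_per_layer["lncRNA"] = self.n_triplets // 2
        for layer, need in min_per_layer.items():
            if self.n_features[layer] < need:
                raise ValueError(
                    f"n_features[{layer!r}] too small for n_triplets={self.n_triplets}"
                )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))

    @property
    def sample_ids(self) -> list[str]:
        return [f"GF_{i + 1}" for i in range(2 * self.n_samples_per_condition)]

    @property
    def conditions(self) -> pd.Series:
        m = self.n_samples_per_condition
        return pd.Series(["GF_C"] * m + ["GF_T"] * m, index=self.sample_ids)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SynthConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SynthConfig field(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside the generated data."""

    planted_de: set = field(default_factory=set)  # (layer, feature_id, direction)
    planted_triplets: set = field(default_factory=set)  # (ceRNA, layer, miRNA, mRNA)
    circ_truth: dict = field(default_factory=dict)  # candidate_id -> criterion map
    latent_log2_means: dict = field(default_factory=dict)  # layer -> DataFrame
    feature_ids: dict = field(default_factory=dict)  # layer -> list


# -- counts --------------------------------------------------------------------


def generate_counts(config: SynthConfig) -> tuple[dict[str, ExpressionMatrix], TruthTable]:
    """Four count matrices plus the truth table.

    Baseline log2 means are uniform on [3, 9]; non-DE features share
    their mean across conditions.  Planted DE features differ by exactly
    ``log2fc_magnitude`` between condition geometric means, with an
    optional within-condition latent profile (block-centered so the
    planted fold change is exact).  Planted triplets derive from a
    shared per-sample latent z: the miRNA follows +z, its mRNA and
    sponge follow -z plus N(0, corr_noise_sd), so miRNA-target latent
    SCC is exactly -1 and sponge-mRNA latent PCC exactly +1 when the
    noise is 0.  Counts are NB with variance mu + phi*mu^2.
    """
    m = config.n_samples_per_condition
    n_samples = 2 * m
    cond_half = np.array([-0.5] * m + [0.5] * m)
    truth = TruthTable()

    prefixes = {"mRNA": "mRNA", "lncRNA": "lnc", "miRNA": "miR", "circRNA": "circ"}
    log2_means: dict[str, np.ndarray] = {}
    ids: dict[str, list[str]] = {}
    lengths: dict[str, np.ndarray] = {}

    n_reserved = _reserved_per_layer(config)
    for layer, stream in LAYER_STREAMS.items():
        rng = config.rng(stream)
        n = config.n_features[layer]
        ids[layer] = [f"{prefixes[layer]}_{i + 1:05d}" for i in range(n)]
        base = rng.uniform(3.0, 9.0, size=n)
        mu = np.tile(base[:, None], (1, n_samples))

        n_free = n - n_reserved[layer]
        n_de = int(round(config.frac_de.get(layer, 0.0) * n))
        n_de = min(n_de, n_free)
        de_idx = rng.choice(n_free, size=n_de, replace=False) if n_de else np.array([], dtype=int)
        directions = rng.choice([1.0, -1.0], size=n_de)
        for i, idx in enumerate(de_idx):
            mu[idx] += directions[i] * config.log2fc_magnitude * cond_half
            truth.planted_de.add(
                (layer, ids[layer][idx], "up" if directions[i] > 0 else "down")
            )
        if n_de and config.de_profile_sd > 0:
            prof = rng.normal(0.0, config.de_profile_sd, size=(n_de, n_samples))
            prof = _balance_blocks(prof, m)
            mu[de_idx] += prof
        lengths[layer] = rng.integers(200, 10_000, size=n) if layer in ("mRNA", "lncRNA") else None
        log2_means[layer] = mu

    # planted ceRNA triplets overwrite reserved tail features of each layer
    trng = config.rng(TRIPLET_STREAM)
    counters = {layer: 0 for layer in LAYER_STREAMS}

    def _take(layer: str) -> int:
        counters[layer] += 1
        return config.n_features[layer] - counters[layer]

    for j in range(config.n_triplets):
        cerna_layer = "circRNA" if j % 2 == 0 else "lncRNA"
        direction = 1.0 if j % 2 == 0 else -1.0  # balanced up/down design
        z = direction * config.triplet_log2fc * cond_half + _draw_triplet_profile(
            trng, m, config.triplet_profile_sd, config.triplet_log2fc
        )
        noise_m = trng.normal(0.0, config.corr_noise_sd, size=n_samples)
        noise_c = trng.normal(0.0, config.corr_noise_sd, size=n_samples)
        base_mi, base_m, base_c = trng.uniform(8.0, 10.0, size=3)

        i_mi, i_m, i_c = _take("miRNA"), _take("mRNA"), _take(cerna_layer)
        log2_means["miRNA"][i_mi] = base_mi + z
        log2_means["mRNA"][i_m] = base_m - z + noise_m
        log2_means[cerna_layer][i_c] = base_c - z + noise_c
        truth.planted_triplets.add(
            (ids[cerna_layer][i_c], cerna_layer, ids["miRNA"][i_mi], ids["mRNA"][i_m])
        )

    matrices: dict[str, ExpressionMatrix] = {}
    for layer, stream in LAYER_STREAMS.items():
        rng = config.rng(stream)
        rng.bit_generator.advance(10**6)  # independent block of the layer stream for sampling
        # features exceeding the mean cap are shifted down as a whole:
        # a per-feature constant preserves fold changes, ranks and
        # correlations exactly, unlike clipping
        mu = log2_means[layer]
        excess = np.maximum(0.0, mu.max(axis=1, keepdims=True) - LOG2_MEAN_CAP)
        mu = mu - excess
        mean = 2.0**mu
        counts = _nb_sample(rng, mean, config.nb_dispersion)
        values = pd.DataFrame(counts, index=ids[layer], columns=config.sample_ids)
        feat_len = (
            pd.Series(lengths[layer], index=ids[layer]) if lengths[layer] is not None else None
        )
        matrices[layer] = ExpressionMatrix(
            layer, values, config.conditions, scale="counts", feature_lengths=feat_len
        )
        truth.latent_log2_means[layer] = pd.DataFrame(
            mu, index=ids[layer], columns=config.sample_ids
        )
        truth.feature_ids[layer] = ids[layer]
    return matrices, truth


def _reserved_per_layer(config: SynthConfig) -> dict[str, int]:
    n_circ = sum(1 for j in range(config.n_triplets) if j % 2 == 0)
    return {
        "miRNA": config.n_triplets,
        "mRNA": config.n_triplets,
        "circRNA": n_circ,
        "lncRNA": config.n_triplets - n_circ,
    }


def _balance_blocks(x: np.ndarray, m: int) -> np.ndarray:
    """Normalize log2 profiles so each condition block's *arithmetic*
    mean on the count scale is exactly 1 -- planted fold changes then
    hold exactly for the condition means the DE caller compares."""
    out = x.copy()
    for sl in (np.s_[:, :m], np.s_[:, m:]):
        out[sl] -= np.log2(np.mean(2.0 ** out[sl], axis=1, keepdims=True))
    return out


def _draw_triplet_profile(
    rng: np.random.Generator,
    m: int,
    sd: float,
    delta: float,
    min_gap: float | None = None,
    max_tries: int = 200,
) -> np.ndarray:
    """Within-condition latent profile for a planted triplet.

    Because the triplet's mRNA and sponge mirror the profile exactly
    (-z), the two condition blocks share one multiset of offsets (block
    T is a random permutation of block C's draws): the arithmetic
    condition means of both 2^z and 2^-z then carry exactly the planted
    fold change.  Draws are additionally rejected until adjacent latent
    values of z = +-delta/2 + b are separated by at least ``min_gap``
    log2 units in either condition orientation, keeping the rank order
    identifiable under count noise; an evenly spaced within-block
    ladder is the (deterministic) fallback.
    """
    if min_gap is None:
        # more samples leave less room per rank step, and the coefficient
        # gate is also more tolerant of single swaps there
        min_gap = 0.9 * 3.0 / m
    shift = np.array([-delta / 2.0] * m + [delta / 2.0] * m)

    def _gaps_ok(full: np.ndarray) -> bool:
        return (
            min(
                np.diff(np.sort(full + shift)).min(),
                np.diff(np.sort(full - shift)).min(),
            )
            >= min_gap
        )

    if sd > 0:
        for _ in range(max_tries):
            b = rng.normal(0.0, sd, size=m)
            full = np.concatenate([b, b[rng.permutation(m)]])
            if _gaps_ok(full):
                return full
    spacing = max(min_gap * 1.5, sd * 3.0 / m)
    for _ in range(50):  # nudge the ladder until no cross-condition collision
        ladder = (np.arange(m) - (m - 1) / 2.0) * spacing
        full = np.concatenate([ladder, ladder[rng.permutation(m)]])
        if _gaps_ok(full):
            return full
        spacing *= 1.13
    return full


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0.0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# -- circRNA candidates --------------------------------------------------------


def generate_circ_candidates(config: SynthConfig) -> tuple[list[CircCandidate], TruthTable]:
    """Candidate records with per-criterion truth verdicts.

    The first 14 records (when requested) are deterministic boundary
    fixtures -- a template passing every filter plus one single-field
    violation per criterion and one boundary pass per criterion -- so
    every criterion is exercised in both directions; the rest are
    random.  The truth verdicts are evaluated at generation time with
    plain, independent predicate expressions.
    """
    rng = config.rng(CIRC_STREAM)
    n = config.n_circ_candidates
    n_samples = 2 * config.n_samples_per_condition
    samples = config.sample_ids
    half = int(n_samples / 2)

    records: list[CircCandidate] = []
    fixtures = _boundary_fixtures(n_samples) if n >= 14 else []
    for i in range(n):
        if i < len(fixtures):
            fields = fixtures[i]
        else:
            length = (
                int(rng.integers(200, 5000))
                if rng.random() < 0.8
                else int(rng.integers(80_000, 150_000))
            )
            fields = {
                "breakpoint_count": int(rng.choice([0, 1, 1, 1, 2])),
                "anchor_overlap": int(rng.integers(0, 6)),
                "edit_distance": int(rng.integers(0, 6)),
                "n_uniq": int(rng.integers(0, 10)),
                "best_qual_A": int(rng.integers(20, 61)),
                "best_qual_B": int(rng.integers(20, 61)),
                "length": length,
            }
        start = int(rng.integers(0, 1_000_000))
        cand = CircCandidate(
            candidate_id=f"cand_{i + 1:05d}",
            chrom=f"chr{int(rng.integers(1, 30))}",
            start=start,
            end=start + fields["length"],
            strand="+" if rng.random() < 0.5 else "-",
            breakpoint_count=fields["breakpoint_count"],
            anchor_overlap=fields["anchor_overlap"],
            edit_distance=fields["edit_distance"],
            n_uniq=fields["n_uniq"],
            best_qual_A=fields["best_qual_A"],
            best_qual_B=fields["best_qual_B"],
            per_sample_counts={s: int(c) for s, c in zip(samples, rng.poisson(3.0, n_samples))},
        )
        records.append(cand)

    truth = TruthTable()
    for cand in records:
        verdict = {
            "a": cand.breakpoint_count == 1,
            "b": cand.anchor_overlap <= 2,
            "c": cand.edit_distance <= 2,
            "d": cand.n_uniq > 2,
            "e": cand.best_qual_A > 35 or cand.best_qual_B > 35,
            "f": cand.n_uniq > half,
            "g": (cand.end - cand.start) < 100_000,
        }
        verdict["overall"] = all(verdict.values())
        truth.circ_truth[cand.candidate_id] = verdict
    return records, truth


def _boundary_fixtures(n_samples: int) -> list[dict]:
    half = int(n_samples / 2)
    template = {
        "breakpoint_count": 1,
        "anchor_overlap": 2,
        "edit_distance": 2,
        "n_uniq": max(3, half + 1),
        "best_qual_A": 40,
        "best_qual_B": 30,
        "length": 99_999,
    }
    violations = [
        {"breakpoint_count": 2},
        {"anchor_overlap": 3},
        {"edit_distance": 3},
        {"n_uniq": 2},
        {"best_qual_A": 35, "best_qual_B": 35},
        {"n_uniq": half},
        {"length": 100_000},
    ]
    fixtures = [dict(template)]
    for v in violations:
        rec = dict(template)
        rec.update(v)
        fixtures.append(rec)
    # boundary passes: smallest values still admitted
    for v in (
        {"anchor_overlap": 0},
        {"edit_distance": 0},
        {"n_uniq": max(3, half + 1)},
        {"best_qual_A": 36, "best_qual_B": 20},
        {"best_qual_A": 20, "best_qual_B": 36},
        {"length": 200},
    ):
        rec = dict(template)
        rec.update(v)
        fixtures.append(rec)
    return fixtures


# -- prediction tables ---------------------------------------------------------


def generate_prediction_tables(
    truth: TruthTable, config: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Three simulated miRNA-target prediction sources.

    Every true (planted) miRNA-mRNA pair enters each table
    independently with probability ``pred_sensitivity``; decoy pairs
    (drawn once from non-planted miRNA x mRNA combinations) enter with
    probability ``1 - pred_specificity``.
    """
    if not truth.feature_ids:
        raise ValueError("truth table carries no feature ids; run generate_counts first")
    true_pairs = sorted({(mi, mr) for (_, _, mi, mr) in truth.planted_triplets})

    decoy_rng = config.rng(ANNOTATION_STREAM + 1)
    mirnas = truth.feature_ids["miRNA"]
    mrnas = truth.feature_ids["mRNA"]
    decoys: set[tuple[str, str]] = set()
    target_n = min(config.n_decoy_pairs, max(0, len(mirnas) * len(mrnas) - len(true_pairs)))
    while len(decoys) < target_n:
        pair = (
            mirnas[int(decoy_rng.integers(len(mirnas)))],
            mrnas[int(decoy_rng.integers(len(mrnas)))],
        )
        if pair not in true_pairs:
            decoys.add(pair)
    decoys = sorted(decoys)

    tables = []
    for stream in PREDICTION_STREAMS:
        rng = config.rng(stream)
        rows = [p for p in true_pairs if rng.random() < config.pred_sensitivity]
        rows += [p for p in decoys if rng.random() < 1.0 - config.pred_specificity]
        tables.append(
            pd.DataFrame(sorted(rows), columns=["miRNA_id", "target_id"]).astype(str)
        )
    return tables[0], tables[1], tables[2]


# -- annotation ----------------------------------------------------------------


def generate_annotation(
    truth: TruthTable,
    config: SynthConfig,
    n_terms: int = 25,
    term_size: tuple[int, int] = (10, 40),
    n_enriched: int = 3,
) -> list[AnnotationSet]:
    """Synthetic GMT-style gene sets over the mRNA universe.

    The first ``n_enriched`` terms are seeded with the planted DE and
    triplet mRNAs (an enrichment signal); the rest are uniform draws.
    """
    rng = config.rng(ANNOTATION_STREAM)
    mrnas = list(truth.feature_ids.get("mRNA", []))
    if not mrnas:
        raise ValueError("truth table carries no mRNA ids; run generate_counts first")
    interesting = sorted(
        {fid for (layer, fid, _) in truth.planted_de if layer == "mRNA"}
        | {mr for (_, _, _, mr) in truth.planted_triplets}
    )
    terms = []
    for t in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        if t < n_enriched and interesting:
            n_sig = min(len(interesting), max(2, size // 2))
            chosen = list(rng.choice(interesting, size=n_sig, replace=False))
            rest = [g for g in mrnas if g not in chosen]
            chosen += list(rng.choice(rest, size=max(0, size - n_sig), replace=False))
        else:
            chosen = list(rng.choice(mrnas, size=size, replace=False))
        terms.append(AnnotationSet(f"TERM:{t + 1:04d}", f"synthetic term {t + 1}", frozenset(chosen)))
    return terms


# -- dataset writer ------------------------------------------------------------


def write_dataset(
    outdir: str | Path,
    matrices: dict[str, ExpressionMatrix],
    truth: TruthTable,
    candidates: list[CircCandidate] | None = None,
    predictions: tuple[pd.DataFrame, ...] | None = None,
) -> None:
    """Write matrices, condition map, truth, candidates and predictions as TSV."""
    from cernet.circfilter import candidates_to_frame, write_candidates_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for layer, mat in matrices.items():
        mat.to_tsv(outdir / f"counts_{layer}.tsv")
        if mat.feature_lengths is not None:
            mat.feature_lengths.rename("length_bp").to_csv(
                outdir / f"lengths_{layer}.tsv", sep="\t", index_label="feature_id"
            )
    first = next(iter(matrices.values()))
    write_condition_map(first.conditions, outdir / "conditions.tsv")

    pd.DataFrame(
        sorted(truth.planted_de), columns=["layer", "feature_id", "direction"]
    ).to_csv(outdir / "truth_planted_de.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.planted_triplets),
        columns=["ceRNA_id", "ceRNA_layer", "miRNA_id", "mRNA_id"],
    ).to_csv(outdir / "truth_triplets.tsv", sep="\t", index=False)

    if candidates is not None:
        write_candidates_tsv(candidates_to_frame(candidates), outdir / "circ_candidates.tsv")
    if truth.circ_truth:
        rows = [{"candidate_id": cid, **v} for cid, v in sorted(truth.circ_truth.items())]
        pd.DataFrame(rows).to_csv(outdir / "truth_circ.tsv", sep="\t", index=False)
    if predictions is not None:
        for name, table in zip(("rnahybrid", "miranda", "targetscan"), predictions):
            table.to_csv(outdir / f"predictions_{name}.tsv", sep="\t", index=False)
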