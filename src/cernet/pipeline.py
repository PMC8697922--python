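"""End-to-end orchestration: simulate -> normalize -> DE -> filter -> network.

Every stage consumes and produces plain TSV files in the run directory,
so any stage can be re-run from disk; the machine-readable
``report.json`` collects per-stage row counts and the normalized
configuration.  Identical config + seed gives byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from cernet import circfilter, cernanet, diffexpr, enrich, quantnorm, synthio, targetlink
from cernet.matrix import ExpressionMatrix, read_condition_map

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "PipelineError"]

#: analysis thresholds default to the published protocol constants
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": True,
    "layers": ["mRNA", "lncRNA", "miRNA", "circRNA"],
    "thresholds": {
        "log2fc": 1.0,
        "fdr": 0.05,
        "p_value": 0.05,
        "scc": -0.7,
        "pcc": 0.9,
        "corrected_p": 0.05,
    },
    "circ_filters": {
        "breakpoint": 1,
        "max_anchor_overlap": 2,
        "max_edit_distance": 2,
        "min_uniq_reads": 2,
        "min_qual": 35,
        "max_length": 100_000,
    },
    "synth": {},  # SynthConfig overrides
    "inputs": {},  # counts_<layer>, lengths_<layer>, conditions, circ_candidates,
    #              predictions (3 paths), annotation_gmt
    "require_predictions_for_cerna": False,
    # correlations are computed on log2(x + 1) of the normalized values;
    # ranks (SCC) are unaffected, and Pearson coexpression then reflects
    # proportional co-variation rather than being dominated by the most
    # abundant sample
    "log_transform_correlations": True,
}


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def validate_config(config: dict | None, strict: bool = True) -> dict:
    """Fill defaults, reject unknown keys and out-of-range thresholds."""
    config = dict(config or {})
    out = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    known = set(DEFAULT_CONFIG)
    unknown = set(config) - known
    if unknown:
        if strict:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        logger.warning("ignoring unknown config key(s): %s", sorted(unknown))
    for key in known & set(config):
        if isinstance(DEFAULT_CONFIG[key], dict) and key != "synth":
            sub_unknown = set(config[key]) - set(DEFAULT_CONFIG[key])
            if sub_unknown and key != "inputs":
                if strict:
                    raise ValueError(f"unknown {key} key(s): {sorted(sub_unknown)}")
                logger.warning("ignoring unknown %s key(s): %s", key, sorted(sub_unknown))
            out[key].update({k: v for k, v in config[key].items()
                            if key == "inputs" or k in DEFAULT_CONFIG[key]})
        else:
            out[key] = config[key]

    thr = out["thresholds"]
    if thr["scc"] >= 0:
        raise ValueError("thresholds.scc must be negative (anti-correlation gate)")
    if not -1.0 <= thr["scc"]:
        raise ValueError("thresholds.scc must lie in [-1, 0)")
    if not 0.0 < thr["pcc"] <= 1.0:
        raise ValueError("thresholds.pcc must lie in (0, 1]")
    for name in ("fdr", "p_value", "corrected_p"):
        if not 0.0 < thr[name] <= 1.0:
            raise ValueError(f"thresholds.{name} must lie in (0, 1]")
    if thr["log2fc"] < 0:
        raise ValueError("thresholds.log2fc must be nonnegative")
    out["synth"] = dict(out.get("synth") or {})
    return out


def run_pipeline(config: dict | None, outdir: str | Path, strict: bool = True) -> dict:
    """Execute the full analysis and return the run report (also written
    to ``report.json``)."""
    cfg = validate_config(config, strict=strict)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg, "stages": {}}

    matrices, truth, candidates, predictions, annotation = _stage_inputs(cfg, outdir)
    report["stages"]["inputs"] = {
        "features": {layer: len(m.values) for layer, m in matrices.items()},
        "samples": len(next(iter(matrices.values())).sample_ids),
        "circ_candidates": len(candidates) if candidates is not None else 0,
    }

    normalized = _stage_normalize(cfg, matrices, outdir)
    report["stages"]["normalize"] = {layer: mat.scale for layer, mat in normalized.items()}

    de_sets = _stage_de(cfg, matrices, outdir)
    report["stages"]["de"] = {
        layer: {
            "n_de": int(df["is_de"].sum()),
            "n_up": int((df["is_de"] & (df["direction"] == "up")).sum()),
            "n_down": int((df["is_de"] & (df["direction"] == "down")).sum()),
        }
        for layer, df in de_sets.items()
    }

    if candidates is not None:
        verdicts, rpm = _stage_circfilter(cfg, candidates, matrices, outdir)
        report["stages"]["circ_filter"] = {
            "candidates": len(verdicts),
            "passing": int(verdicts["overall"].sum()),
        }

    pairs_mrna, pairs_cerna = _stage_pairs(cfg, de_sets, normalized, predictions, outdir)
    report["stages"]["pairs"] = {
        "mirna_mrna_evaluated": len(pairs_mrna),
        "mirna_mrna_kept": int(pairs_mrna["kept"].sum()) if len(pairs_mrna) else 0,
        "cerna_mirna_evaluated": len(pairs_cerna),
        "cerna_mirna_kept": int(pairs_cerna["kept"].sum()) if len(pairs_cerna) else 0,
    }

    triplets, network = _stage_network(cfg, de_sets, pairs_mrna, pairs_cerna, normalized, outdir)
    edge_types = {}
    for _, _, d in network.graph.edges(data=True):
        edge_types[d["edge_type"]] = edge_types.get(d["edge_type"], 0) + 1
    report["stages"]["network"] = {
        "triplets": len(triplets),
        "nodes": network.node_count(),
        "edges": network.edge_count(),
        "edges_by_type": dict(sorted(edge_types.items())),
        "hubs": [list(h) for h in cernanet.degree_and_hubs(network, 3)],
    }

    if annotation is not None:
        enr = _stage_enrich(cfg, de_sets, triplets, matrices, annotation, outdir)
        report["stages"]["enrich"] = {
            name: {"terms": len(df), "significant": int(df["significant"].sum()) if len(df) else 0}
            for name, df in enr.items()
        }

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


# -- stages --------------------------------------------------------------------


def _correlation_lookup(cfg: dict, normalized: dict) -> dict[str, np.ndarray]:
    sample_order = next(iter(normalized.values())).sample_ids
    lookup: dict[str, np.ndarray] = {}
    for mat in normalized.values():
        if mat.sample_ids != sample_order:
            raise ValueError("sample order differs between layers")
        lookup.update(mat.expression_lookup())
    if cfg.get("log_transform_correlations", True):
        lookup = {k: np.log2(v + 1.0) for k, v in lookup.items()}
    return lookup


def _stage_inputs(cfg: dict, outdir: Path):
    try:
        if cfg["synthetic"]:
            synth_cfg = synthio.SynthConfig.from_dict({"seed": cfg["seed"], **cfg["synth"]})
            matrices, truth = synthio.generate_counts(synth_cfg)
            candidates, circ_truth = synthio.generate_circ_candidates(synth_cfg)
            truth.circ_truth = circ_truth.circ_truth
            predictions = synthio.generate_prediction_tables(truth, synth_cfg)
            annotation = synthio.generate_annotation(truth, synth_cfg)
            synthio.write_dataset(outdir / "inputs", matrices, truth, candidates, predictions)
            enrich.write_gmt(annotation, outdir / "inputs" / "annotation.gmt")
            return matrices, truth, candidates, predictions, annotation
        inputs = cfg["inputs"]
        for req in ("conditions",):
            if req not in inputs or not Path(inputs[req]).exists():
                raise FileNotFoundError(f"required input {req!r} missing")
        conditions = read_condition_map(inputs["conditions"])
        matrices = {}
        for layer in cfg["layers"]:
            key = f"counts_{layer}"
            if key not in inputs or not Path(inputs[key]).exists():
                raise FileNotFoundError(f"required input {key!r} missing")
            mat = ExpressionMatrix.from_tsv(inputs[key], layer, conditions)
            lkey = f"lengths_{layer}"
            if lkey in inputs:
                lengths = pd.read_csv(inputs[lkey], sep="\t", index_col="feature_id")["length_bp"]
                mat.feature_lengths = lengths
            matrices[layer] = mat
        candidates = None
        if "circ_candidates" in inputs:
            df = circfilter.read_candidates_tsv(inputs["circ_candidates"])
            candidates = df
        predictions = None
        if "predictions" in inputs:
            paths = inputs["predictions"]
            if len(paths) != 3:
                raise ValueError("exactly three prediction tables are required")
            predictions = tuple(targetlink.read_prediction_tsv(p) for p in paths)
        annotation = enrich.read_gmt(inputs["annotation_gmt"]) if "annotation_gmt" in inputs else None
        return matrices, None, candidates, predictions, annotation
    except Exception as exc:  # noqa: BLE001 - re-labelled with the stage name
        raise PipelineError("inputs", str(exc)) from exc


def _stage_normalize(cfg, matrices, outdir: Path):
    try:
        normdir = outdir / "normalized"
        normdir.mkdir(exist_ok=True)
        normalized = {}
        for layer, mat in matrices.items():
            if layer in ("mRNA", "lncRNA") and mat.feature_lengths is not None:
                norm = quantnorm.fpkm_matrix(mat)
            elif layer == "miRNA":
                norm = quantnorm.tpm_matrix(mat)
            else:
                norm = quantnorm.rpm_matrix(mat)
            norm.to_tsv(normdir / f"{layer}_{norm.scale}.tsv")
            normalized[layer] = norm
        return normalized
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc


def _stage_de(cfg, matrices, outdir: Path):
    try:
        dedir = outdir / "de"
        dedir.mkdir(exist_ok=True)
        thr = cfg["thresholds"]
        de_sets = {}
        for layer, mat in matrices.items():
            alpha = thr["fdr"] if diffexpr.DE_RULES[layer][0] == "fdr" else thr["p_value"]
            df = diffexpr.call_de(mat, layer, log2fc_threshold=thr["log2fc"], alpha=alpha)
            df.to_csv(dedir / f"{layer}.tsv", sep="\t")
            de_sets[layer] = df
            logger.info("DE %s: %d/%d features", layer, int(df["is_de"].sum()), len(df))
        return de_sets
    except Exception as exc:
        raise PipelineError("de", str(exc)) from exc


def _stage_circfilter(cfg, candidates, matrices, outdir: Path):
    try:
        circdir = outdir / "circ"
        circdir.mkdir(exist_ok=True)
        n_samples = len(next(iter(matrices.values())).sample_ids)
        frame = (
            candidates
            if isinstance(candidates, pd.DataFrame)
            else circfilter.candidates_to_frame(candidates)
        )
        verdicts = circfilter.apply_filters(frame, n_samples)
        verdicts.to_csv(circdir / "verdicts.tsv", sep="\t")
        circfilter.write_bed(frame, verdicts, circdir / "passing.bed")
        count_cols = [c for c in frame.columns if c.startswith("count_")]
        totals = frame[count_cols].sum()
        totals.index = [c.removeprefix("count_") for c in count_cols]
        rpm = None
        if (totals > 0).all() and verdicts["overall"].any():
            conditions = next(iter(matrices.values())).conditions
            rpm = circfilter.quantify_rpm(frame, verdicts, totals, conditions)
            rpm.to_tsv(circdir / "passing_RPM.tsv")
        return verdicts, rpm
    except Exception as exc:
        raise PipelineError("circ_filter", str(exc)) from exc


def _stage_pairs(cfg, de_sets, normalized, predictions, outdir: Path):
    try:
        pairdir = outdir / "pairs"
        pairdir.mkdir(exist_ok=True)
        thr = cfg["thresholds"]
        lookup = _correlation_lookup(cfg, normalized)

        de_mirnas = set(de_sets["miRNA"].index[de_sets["miRNA"]["is_de"]])
        de_mrnas = set(de_sets["mRNA"].index[de_sets["mRNA"]["is_de"]])

        if predictions is not None:
            predicted = targetlink.intersect_predictions(*predictions)
        else:
            predicted = set()
        candidate_pairs = {
            (mi, mr) for (mi, mr) in predicted if mi in de_mirnas and mr in de_mrnas
        }
        pairs_mrna = targetlink.select_negative_pairs(
            candidate_pairs, lookup, scc_threshold=thr["scc"], alpha=thr["p_value"]
        )
        targetlink.write_pairs_tsv(pairs_mrna, pairdir / "mirna_mrna.tsv")

        cerna_rows = []
        for layer in ("lncRNA", "circRNA"):
            if layer not in de_sets:
                continue
            de_cernas = set(de_sets[layer].index[de_sets[layer]["is_de"]])
            cand = {(mi, ce) for mi in de_mirnas for ce in de_cernas}
            if cfg["require_predictions_for_cerna"] and predictions is not None:
                cand = {p for p in cand if p in predicted}
            gated = targetlink.select_negative_pairs(
                cand, lookup, scc_threshold=thr["scc"], alpha=thr["p_value"]
            )
            gated["target_layer"] = layer
            cerna_rows.append(gated)
        pairs_cerna = (
            pd.concat(cerna_rows, ignore_index=True)
            if cerna_rows
            else pd.DataFrame(
                {"miRNA_id": [], "target_id": [], "scc": [], "p_value": [],
                 "n": [], "kept": pd.Series([], dtype=bool), "target_layer": []}
            )
        )
        targetlink.write_pairs_tsv(pairs_cerna, pairdir / "cerna_mirna.tsv")
        return pairs_mrna, pairs_cerna
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("pairs", str(exc)) from exc


def _stage_network(cfg, de_sets, pairs_mrna, pairs_cerna, normalized, outdir: Path):
    try:
        netdir = outdir / "network"
        netdir.mkdir(exist_ok=True)
        thr = cfg["thresholds"]
        lookup = _correlation_lookup(cfg, normalized)
        triplets, network = cernanet.build_network(
            de_sets,
            pairs_mrna,
            pairs_cerna,
            lookup,
            pcc_threshold=thr["pcc"],
            alpha=thr["p_value"],
        )
        cernanet.triplets_to_frame(triplets).to_csv(netdir / "triplets.tsv", sep="\t", index=False)
        cernanet.export_network(network, netdir / "network.graphml", "graphml")
        cernanet.export_network(network, netdir / "network.sif", "sif")
        return triplets, network
    except Exception as exc:
        raise PipelineError("network", str(exc)) from exc


def _stage_enrich(cfg, de_sets, triplets, matrices, annotation, outdir: Path):
    try:
        enrdir = outdir / "enrich"
        enrdir.mkdir(exist_ok=True)
        population = set(matrices["mRNA"].feature_ids)
        studies = {
            "de_mrna": set(de_sets["mRNA"].index[de_sets["mRNA"]["is_de"]]),
            "crn_mrna": {t.mRNA_id for t in triplets},
        }
        results = {}
        for name, study in studies.items():
            if not study:
                results[name] = pd.DataFrame(
                    columns=["term_id", "term_name", "k", "K", "n", "N",
                             "p_value", "corrected_p", "significant"]
                )
            else:
                results[name] = enrich.hypergeom_enrich(
                    study, population, annotation, alpha=cfg["thresholds"]["corrected_p"]
                )
            results[name].to_csv(enrdir / f"{name}.tsv", sep="\t", index=False)
        return results
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc
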