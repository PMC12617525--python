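"""End-to-end orchestration with a single declarative config.

Stage order: simulate -> preprocess -> features -> predict -> cluster ->
diff; the spatial arm runs independently. Every stochastic stage consumes a
named sub-seed derived from the master seed, so a full run is reproducible
and two runs with the same config and seed produce byte-identical TSV/JSON
outputs (the manifest's timestamps aside).
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path
from typing import Mapping

from . import complexes as cx
from . import differential as diff
from . import io as cio
from . import ppi
from . import preprocess as prep
from . import similarity as sim
from . import spatial as sp
from . import synth

__version__ = "0.1.0"

DEFAULT_CONFIG: dict = {
    "simulate": {
        "enabled": True,
        "n_complexes": 50,
        "complex_size_range": [3, 8],
        "n_background_proteins": 100,
        "n_fractions": 96,
        "peak_width_range": [3.0, 6.0],
        "abundance_scale": 100.0,
        "count_noise": 0.1,
        "dropout_prob": 0.2,
        "n_engines": 3,
        "extract": "Mt",
        "rewiring": None,  # None -> synth.DEFAULT_REWIRING
    },
    "preprocess": {"mode": "both", "log2": False},
    "features": {"metrics": None, "prefilter_floor": None},
    "predict": {
        "models": ["rf", "glm", "svm", "ensemble"],
        "folds": 5,
        "negative_ratio": 1.0,
        "threshold_rule": "youden",
        "reference_gmt": None,      # required when simulate is disabled
        "compartments_tsv": None,
    },
    "cluster": {
        "d_grid": [0.2, 0.3, 0.45],
        "o_grid": [0.5, 0.65, 0.8],
        "penalty": 2.0,
        "min_size": 3,
    },
    "diff": {"reference_genotype": "WT", "n_perm": 1000,
             "per_fraction_ranking": False},
    "spatial": {
        "enabled": False,
        "n_per_group": 20,
        "n_genes": 2000,
        "deg_frac": 0.2,
        "effect_size": 2.0,
        "region": "SN",
        "marker_floor": 1.0,
        "p_cut": 0.05,
        "top_frac": 0.20,
        "test": "welch",
    },
}


class ConfigError(ValueError):
    pass


def merge_config(overrides: Mapping | None = None) -> dict:
    """Default config overlaid with ``overrides``; unknown keys rejected."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if not overrides:
        return config
    bad: list[str] = []
    for section, values in overrides.items():
        if section not in config:
            bad.append(section)
            continue
        if not isinstance(values, Mapping):
            bad.append(section)
            continue
        for key, value in values.items():
            if key not in config[section]:
                bad.append(f"{section}.{key}")
            else:
                config[section][key] = value
    if bad:
        raise ConfigError(f"unknown config key(s): {sorted(bad)}")
    return config


def validate_config(config: Mapping) -> None:
    if not config["simulate"]["enabled"]:
        if not config["predict"]["reference_gmt"]:
            raise ConfigError(
                "predict.reference_gmt is required when simulate.enabled is false")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic named sub-seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: Mapping | None, outdir: str | Path,
                 master_seed: int = 0) -> dict:
    """Execute the CF-MS stages (and optionally the spatial arm); return the
    run manifest (also written to ``outdir/manifest.json``)."""
    config = merge_config(config) if not _is_merged(config) else copy.deepcopy(config)
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    outputs: dict[str, str] = {}

    def _record(name: str, path: Path) -> None:
        outputs[name] = _digest(path)

    sim_cfg = config["simulate"]
    scfg = synth.SimulationConfig(
        n_complexes=sim_cfg["n_complexes"],
        complex_size_range=tuple(sim_cfg["complex_size_range"]),
        n_background_proteins=sim_cfg["n_background_proteins"],
        n_fractions=sim_cfg["n_fractions"],
        peak_width_range=tuple(sim_cfg["peak_width_range"]),
        abundance_scale=sim_cfg["abundance_scale"],
        count_noise=sim_cfg["count_noise"],
        dropout_prob=sim_cfg["dropout_prob"],
        n_engines=sim_cfg["n_engines"],
        seed=stage_seed(master_seed, "simulate"),
    )
    extract = sim_cfg["extract"]

    # --- simulate -----------------------------------------------------------
    truth = synth.generate_truth(scfg, sim_cfg["rewiring"])
    per_genotype: dict[str, list] = {}
    for genotype in truth.genotypes:
        per_genotype[genotype] = synth.simulate_elution(
            truth, scfg, genotype, extract=extract)
        for m in per_genotype[genotype]:
            path = outdir / f"matrix_{genotype}_{m.engine}.tsv"
            cio.write_matrix(m, path)
            _record(path.name, path)
        gmt = outdir / f"truth_{genotype}.gmt"
        cio.write_gmt(truth.catalogs[genotype], gmt)
        _record(gmt.name, gmt)
    comp_path = outdir / "compartments.tsv"
    cio.write_compartments(truth.compartments, comp_path)
    _record(comp_path.name, comp_path)
    log_path = outdir / "rewiring_log.json"
    cio.write_json_report(
        {"rewiring_log": [list(entry) for entry in truth.rewiring_log]}, log_path)
    _record(log_path.name, log_path)

    reference = truth.catalogs[synth.REFERENCE_GENOTYPE]
    if config["predict"]["reference_gmt"]:
        reference = cio.read_gmt(config["predict"]["reference_gmt"])
    compartments = truth.compartments
    if config["predict"]["compartments_tsv"]:
        compartments = cio.read_compartments(config["predict"]["compartments_tsv"])

    # --- per-genotype: preprocess -> features -> predict -> cluster ---------
    networks: dict[str, cio.ScoredNetwork] = {}
    combined: dict[str, cio.ElutionMatrix] = {}
    predicted: dict[str, cio.ComplexCatalog] = {}
    for genotype in truth.genotypes:
        matrix, report = prep.preprocess_condition(
            per_genotype[genotype], mode=config["preprocess"]["mode"],
            log2_transform=config["preprocess"]["log2"])
        combined[genotype] = matrix
        mpath = outdir / f"combined_{genotype}.tsv"
        cio.write_matrix(matrix, mpath)
        _record(mpath.name, mpath)
        rpath = outdir / f"preprocess_{genotype}.json"
        cio.write_json_report(report.as_dict(), rpath)
        _record(rpath.name, rpath)

        features = sim.compute_features(
            matrix, config["features"]["metrics"],
            config["features"]["prefilter_floor"])

        training = ppi.build_training(
            reference, matrix.proteins,
            negative_ratio=config["predict"]["negative_ratio"],
            seed=stage_seed(master_seed, f"training:{genotype}"))
        scores, cv_report = ppi.train_and_score(
            features, training, models=tuple(config["predict"]["models"]),
            k_folds=config["predict"]["folds"],
            seed=stage_seed(master_seed, f"predict:{genotype}"))
        threshold = ppi.select_threshold(
            cv_report, rule=config["predict"]["threshold_rule"])
        cv_report.threshold = threshold
        cv_report.threshold_rule = config["predict"]["threshold_rule"]
        network = ppi.network_from_scores(
            scores["ensemble"], threshold, genotype=genotype, extract=extract)
        network, plaus = ppi.filter_implausible(network, compartments)
        networks[genotype] = network
        epath = outdir / f"network_{genotype}.tsv"
        cio.write_edges(network, epath)
        _record(epath.name, epath)
        cpath = outdir / f"cv_{genotype}.json"
        cio.write_json_report(
            {**cv_report.as_dict(),
             "n_edges": len(network),
             "n_implausible_removed": len(plaus.removed)}, cpath)
        _record(cpath.name, cpath)

        grid = cx.optimize_params(
            network, reference,
            d_grid=config["cluster"]["d_grid"],
            o_grid=config["cluster"]["o_grid"],
            penalty=config["cluster"]["penalty"],
            min_size=config["cluster"]["min_size"])
        predicted[genotype] = grid.best_catalog
        gpath = outdir / f"predicted_{genotype}.gmt"
        cio.write_gmt(grid.best_catalog, gpath)
        _record(gpath.name, gpath)
        jpath = outdir / f"cluster_grid_{genotype}.json"
        cio.write_json_report(
            {"best": {"d": grid.best_params.d, "o": grid.best_params.o,
                      **grid.best_report.as_dict()},
             "grid": grid.grid_dict()}, jpath)
        _record(jpath.name, jpath)

    # --- differential --------------------------------------------------------
    ref_gt = config["diff"]["reference_genotype"]
    others = [g for g in truth.genotypes if g != ref_gt]
    inter = diff.intersect_networks(networks)
    ipath = outdir / "intersections.json"
    cio.write_json_report(inter.as_dict(), ipath)
    _record(ipath.name, ipath)

    lost = diff.lost_interactions(networks[ref_gt],
                                  [networks[g] for g in others])
    lpath = outdir / "lost_ppis.json"
    cio.write_json_report(lost.as_dict(), lpath)
    _record(lpath.name, lpath)

    gene_sets = {}
    for genotype, catalog in predicted.items():
        for cid, members in catalog.complexes.items():
            gene_sets[f"{genotype}:{cid}"] = members
    if gene_sets:
        consolidated = cio.ComplexCatalog(gene_sets, source="predicted")
        for genotype in others:
            ranking = diff.rank_proteins(
                combined[ref_gt], combined[genotype],
                per_fraction=config["diff"]["per_fraction_ranking"])
            enr = diff.complex_gsea(
                ranking, consolidated, n_perm=config["diff"]["n_perm"],
                seed=stage_seed(master_seed, f"gsea:{genotype}"))
            gpath = outdir / f"gsea_{ref_gt}_vs_{genotype}.json"
            cio.write_json_report(enr.as_dict(), gpath)
            _record(gpath.name, gpath)

    # --- spatial arm ----------------------------------------------------------
    if config["spatial"]["enabled"]:
        run_spatial(config, outdir, master_seed, outputs)

    manifest = {
        "package_version": __version__,
        "master_seed": master_seed,
        "stage_order": ["simulate", "preprocess", "features", "predict",
                        "cluster", "diff"]
                       + (["spatial"] if config["spatial"]["enabled"] else []),
        "config": config,
        "outputs": outputs,
        "started": t0,
        "elapsed_seconds": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n")
    return manifest


def _is_merged(config) -> bool:
    return (isinstance(config, Mapping)
            and set(config) == set(DEFAULT_CONFIG)
            and all(set(config[k]) == set(DEFAULT_CONFIG[k]) for k in config))


def run_spatial(config: Mapping | None, outdir: str | Path,
                master_seed: int = 0,
                outputs: dict[str, str] | None = None) -> dict:
    """Run only the spatial DEG arm; returns summary counts."""
    config = merge_config(config) if not _is_merged(config) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = config["spatial"]
    data, deg_truth = synth.simulate_spots(
        n_per_group=scfg["n_per_group"], n_genes=scfg["n_genes"],
        deg_frac=scfg["deg_frac"], effect_size=scfg["effect_size"],
        seed=stage_seed(master_seed, "spatial"), region=scfg["region"])
    table, degs = sp.deg_pipeline(
        data, region=scfg["region"], marker_floor=scfg["marker_floor"],
        test=scfg["test"], p_cut=scfg["p_cut"], top_frac=scfg["top_frac"])
    tpath = outdir / "deg_scores.tsv"
    table.to_csv(tpath, sep="\t", float_format="%.6g")
    jpath = outdir / "deg_calls.json"
    planted = set(deg_truth)
    recall = (len(planted & set(degs)) / len(planted)) if planted else 0.0
    summary = {"n_genes": len(table), "n_degs": len(degs),
               "n_planted": len(planted),
               "planted_recall": round(recall, 4), "degs": sorted(degs)}
    cio.write_json_report(summary, jpath)
    if outputs is not None:
        outputs[tpath.name] = _digest(tpath)
        outputs[jpath.name] = _digest(jpath)
    return summary
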