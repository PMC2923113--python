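"""Pipeline orchestration: simulate -> detect -> score -> validate -> report.

The pipeline is configured by a nested dictionary (typically read from a
YAML file) whose blocks mirror the stage parameter sets; every default
equals the method's standard parameterization (MCODE node score 0.2,
haircut on, fluff off, max depth 100; confidence and matching-frequency
thresholds 0.5; community size cap 200 with representative subsets of 5).
A single global seed is propagated to every stochastic stage, so identical
(config, seed) pairs produce byte-identical report bundles.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from . import __version__
from .annotate import (
    load_annotation_map,
    load_expression,
    load_obo,
    module_variables,
    write_expression,
    write_obo,
)
from .detect import (
    DetectionParams,
    detect_cpm,
    detect_greedy,
    detect_mcode,
    detect_walktrap,
    size_histogram,
)
from .netio import (
    HTP,
    INT,
    LIT,
    ORTHO,
    load_edgelist,
    read_gmt,
    read_modules,
    write_edgelist,
    write_gmt,
    write_modules,
)
from .score import (
    ConfidenceThresholds,
    assign_confidence,
    classify_permanence,
    crosstalk_score,
)
from .synthetic_data import (
    PlantSpec,
    generate_annotation_layer,
    generate_catalogs,
    generate_expression,
    generate_interactome_classes,
)
from .validate import (
    best_matching_complex,
    class_pr,
    fit_power_law,
    module_pr,
    round_half_away,
)

logger = logging.getLogger("ppimodules")

CLASS_FILES = {LIT: "lit.tsv", ORTHO: "ortho.tsv", HTP: "htp.tsv", INT: "int.tsv"}

DEFAULT_CONFIG: dict[str, Any] = {
    "simulate": {
        "n_plants": 8,
        "plant_size_range": [6, 12],
        "intra_density": 0.9,
        "background_nodes": 300,
        "background_density": 0.005,
        "class_edge_retention": {LIT: 0.9, ORTHO: 0.7, HTP: 0.4},
        "class_extra_noise": {LIT: 0.02, ORTHO: 0.05, HTP: 0.15},
        "permanent_fraction": 0.5,
        "annotation": {"depth": 4, "p_coherent": 0.9, "p_noise": 0.05},
        "expression": {
            "n_tissues": 50,
            "rho_permanent": 0.8,
            "rho_transient": 0.1,
        },
        "catalogs": {"dropout": 0.1, "contamination": 0.1},
    },
    "detect": {
        "methods": ["cpm", "mcode"],
        "classes": [LIT, ORTHO, HTP, INT],
        "cpm_k": 4,
        "mcode": {
            "node_score_cutoff": 0.2,
            "haircut": True,
            "fluff": False,
            "max_depth": 100,
        },
        "walktrap_steps": 4,
    },
    "score": {"go_threshold": 0.5, "cor_threshold": 0.5},
    "validate": {"freq_threshold": 0.5},
    "seed": 0,
    "log_level": "INFO",
}


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


class ConfigError(ValueError):
    pass


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: Optional[str | Path] = None, **overrides: Any) -> dict:
    """Defaults merged with a YAML file and keyword overrides."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        try:
            loaded = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"config {path} is not a mapping")
            config = _deep_merge(config, loaded)
    if overrides:
        config = _deep_merge(config, overrides)
    return config


def _derived_seed(seed: int, offset: int) -> int:
    return (int(seed) + offset) % (2**31 - 1)


def _fmt(value: Optional[float]) -> str:
    return "NA" if value is None else f"{round_half_away(value, 2):.2f}"


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: dict, outdir: Path) -> dict:
    sim = config["simulate"]
    seed = config["seed"]
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    spec = PlantSpec(
        n_plants=sim["n_plants"],
        plant_size_range=tuple(sim["plant_size_range"]),
        intra_density=sim["intra_density"],
        background_nodes=sim["background_nodes"],
        background_density=sim["background_density"],
        class_edge_retention=dict(sim["class_edge_retention"]),
        class_extra_noise=dict(sim["class_extra_noise"]),
        permanent_fraction=sim["permanent_fraction"],
        seed=_derived_seed(seed, 0),
    )
    truth, classes = generate_interactome_classes(spec)
    for label, fname in CLASS_FILES.items():
        write_edgelist(classes[label], inputs / fname)
    truth.to_json(inputs / "truth.json")

    ann = sim["annotation"]
    ontology, annotations = generate_annotation_layer(
        truth,
        depth=ann["depth"],
        p_coherent=ann["p_coherent"],
        p_noise=ann["p_noise"],
        seed=_derived_seed(seed, 1),
    )
    write_obo(ontology, inputs / "ontology.obo")
    from .netio import write_annotations

    write_annotations(annotations.assignments, inputs / "annotations.tsv")

    expr = sim["expression"]
    matrix = generate_expression(
        truth,
        n_tissues=expr["n_tissues"],
        rho_permanent=expr["rho_permanent"],
        rho_transient=expr["rho_transient"],
        seed=_derived_seed(seed, 2),
    )
    write_expression(matrix, inputs / "expression.tsv")

    cat = sim["catalogs"]
    complexes, pathways = generate_catalogs(
        truth,
        dropout=cat["dropout"],
        contamination=cat["contamination"],
        seed=_derived_seed(seed, 3),
    )
    write_gmt(complexes, inputs / "complexes.gmt")
    write_gmt(pathways, inputs / "pathways.gmt")
    return {
        "classes": {label: classes[label].number_of_edges() for label in classes},
        "plants": len(truth.plants),
    }


def _detection_params(config: dict) -> DetectionParams:
    mc = config["detect"]["mcode"]
    return DetectionParams(
        mcode_node_score_cutoff=mc["node_score_cutoff"],
        mcode_haircut=mc["haircut"],
        mcode_fluff=mc["fluff"],
        mcode_max_depth=mc["max_depth"],
        walktrap_steps=config["detect"]["walktrap_steps"],
    )


def stage_detect(config: dict, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    moddir = outdir / "modules"
    moddir.mkdir(parents=True, exist_ok=True)
    params = _detection_params(config)
    counts: dict[str, int] = {}
    for label in config["detect"]["classes"]:
        path = inputs / CLASS_FILES[label]
        if not path.exists():
            raise PipelineStageError("detect", f"missing edge list {path}")
        network = load_edgelist(path, label)
        for method in config["detect"]["methods"]:
            if method == "cpm":
                modules = detect_cpm(network, config["detect"]["cpm_k"])
            elif method == "mcode":
                modules = detect_mcode(network, params)
            elif method == "maxmod":
                modules, _ = detect_greedy(network)
            elif method == "walktrap":
                modules, _ = detect_walktrap(network, params.walktrap_steps)
            else:
                raise PipelineStageError("detect", f"unknown method {method!r}")
            write_modules(modules, moddir / f"{method}_{label.lower()}.tsv")
            counts[f"{method}/{label}"] = len(modules)
    return counts


def stage_score(config: dict, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    moddir = outdir / "modules"
    scoredir = outdir / "scores"
    scoredir.mkdir(parents=True, exist_ok=True)
    obo_path = inputs / "ontology.obo"
    if not obo_path.exists():
        raise PipelineStageError("score", f"missing ontology {obo_path}")
    ontology = load_obo(obo_path)
    annotations = load_annotation_map(inputs / "annotations.tsv", ontology)
    expression = load_expression(inputs / "expression.tsv")
    thresholds = ConfidenceThresholds(
        go_threshold=config["score"]["go_threshold"],
        cor_threshold=config["score"]["cor_threshold"],
    )
    label_counts: dict[str, int] = {}
    for label in config["detect"]["classes"]:
        network = load_edgelist(inputs / CLASS_FILES[label], label)
        for method in config["detect"]["methods"]:
            table = moddir / f"{method}_{label.lower()}.tsv"
            if not table.exists():
                raise PipelineStageError("score", f"missing module table {table}")
            modules = read_modules(table)
            out = scoredir / f"{method}_{label.lower()}.tsv"
            with out.open("w") as fh:
                fh.write(
                    "module_id\tn\tn_ex\tex_mean\tcor_mean\tmf_mean\tbp_mean"
                    "\tcc_mean\tconfidence\tpermanence\tcrosstalk\n"
                )
                for module in modules:
                    v = module_variables(
                        module, ontology, annotations, expression, network
                    )
                    conf = assign_confidence(v, thresholds)
                    perm = classify_permanence(v, config["score"]["cor_threshold"])
                    xt = crosstalk_score(module, network)
                    label_counts[conf] = label_counts.get(conf, 0) + 1
                    fh.write(
                        f"{v.module_id}\t{v.n}\t{v.n_ex}\t{_fmt(v.ex_mean)}"
                        f"\t{_fmt(v.cor_mean)}\t{_fmt(v.mf_mean)}"
                        f"\t{_fmt(v.bp_mean)}\t{_fmt(v.cc_mean)}"
                        f"\t{conf}\t{perm}\t{_fmt(xt)}\n"
                    )
    return label_counts


def stage_validate(config: dict, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    moddir = outdir / "modules"
    valdir = outdir / "validation"
    valdir.mkdir(parents=True, exist_ok=True)
    gmt = inputs / "complexes.gmt"
    if not gmt.exists():
        raise PipelineStageError("validate", f"missing complex catalog {gmt}")
    complexes = read_gmt(gmt)
    threshold = config["validate"]["freq_threshold"]

    summary_rows = []
    sizes_by_method: dict[str, list[int]] = {}
    for label in config["detect"]["classes"]:
        for method in config["detect"]["methods"]:
            table = moddir / f"{method}_{label.lower()}.tsv"
            modules = read_modules(table)
            sizes_by_method.setdefault(method, []).extend(m.size for m in modules)
            per_module = valdir / f"{method}_{label.lower()}.tsv"
            with per_module.open("w") as fh:
                fh.write("module_id\tbest_complex\tfrequency\tprecision\trecall\n")
                for module in modules:
                    best = best_matching_complex(module, complexes)
                    if best is None:
                        fh.write(f"{module.module_id}\tNA\t0.00\tNA\tNA\n")
                        continue
                    name, freq = best
                    counts = module_pr(module, complexes[name])
                    fh.write(
                        f"{module.module_id}\t{name}\t{_fmt(freq)}"
                        f"\t{_fmt(counts.precision)}\t{_fmt(counts.recall)}\n"
                    )
            if modules:
                summary = class_pr(modules, complexes, threshold)
                summary_rows.append(
                    (
                        method,
                        label,
                        summary.MM,
                        summary.PM,
                        f"{summary.MC:.4f}",
                        summary.KC,
                        _fmt(summary.precision_prime),
                        _fmt(summary.recall_prime),
                    )
                )
            else:
                summary_rows.append((method, label, 0, 0, "0.0000", 0, "0.00", "NA"))

    with (valdir / "class_summary.tsv").open("w") as fh:
        fh.write("method\tclass\tMM\tPM\tMC\tKC\tprecision_prime\trecall_prime\n")
        for row in summary_rows:
            fh.write("\t".join(str(c) for c in row) + "\n")

    fits: dict[str, Any] = {}
    for method, sizes in sorted(sizes_by_method.items()):
        hist = size_histogram(read_modules(moddir / f"{method}_int.tsv")) if (
            moddir / f"{method}_int.tsv"
        ).exists() else {}
        entry: dict[str, Any] = {
            "n_modules": len(sizes),
            "int_histogram": {str(k): v for k, v in sorted(hist.items())},
        }
        try:
            fit = fit_power_law(sizes)
            entry["power_law"] = {
                "alpha": round(fit.alpha, 4),
                "x_min": fit.x_min,
                "ks_distance": round(fit.ks_distance, 4),
            }
        except ValueError as exc:
            entry["power_law"] = None
            entry["power_law_note"] = str(exc)
        fits[method] = entry
    (valdir / "size_distributions.json").write_text(
        json.dumps(fits, indent=2, sort_keys=True)
    )
    return {"classes_validated": len(summary_rows)}


def stage_report(config: dict, outdir: Path, stage_info: dict) -> dict:
    manifest = {
        "package": "ppimodules",
        "version": __version__,
        "seed": config["seed"],
        "config": config,
        "stages": stage_info,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


_STAGES = ("simulate", "detect", "score", "validate", "report")


def run_pipeline(
    config: dict, outdir: str | Path, stages: Optional[list[str]] = None
) -> dict:
    """Run the configured stages in order, writing a report bundle.

    A failure aborts with a stage-named error; outputs of earlier stages are
    retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages is not None else list(_STAGES)
    for s in stages:
        if s not in _STAGES:
            raise ConfigError(f"unknown stage {s!r}")
    info: dict[str, Any] = {}
    for stage in _STAGES:
        if stage not in stages:
            continue
        t0 = time.monotonic()
        try:
            if stage == "simulate":
                info[stage] = stage_simulate(config, outdir)
            elif stage == "detect":
                info[stage] = stage_detect(config, outdir)
            elif stage == "score":
                info[stage] = stage_score(config, outdir)
            elif stage == "validate":
                info[stage] = stage_validate(config, outdir)
            elif stage == "report":
                stage_report(config, outdir, info)
                info[stage] = {"written": "manifest.json"}
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise PipelineStageError(stage, str(exc)) from exc
        logger.info(
            "stage %s done in %.2fs: %s", stage, time.monotonic() - t0, info[stage]
        )
    return info
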