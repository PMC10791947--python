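"""Run-configuration schema: YAML/dict in, validated CrossValidatorSpec out.

Unknown keys are rejected with their full dotted path before any compute
starts.
"""

from __future__ import annotations

from typing import Optional

from .crossval import CrossValidatorSpec, VALID_METRICS
from .datasource import DataSourceSpec
from .errors import ConfigError

__all__ = ["build_spec_from_config", "TOP_LEVEL_KEYS"]

TOP_LEVEL_KEYS = {
    "binned", "datasource", "preprocessors", "classifier", "metrics",
    "cross_validator", "seed", "output", "result_name",
}
_DS_KEYS = {
    "type", "label", "num_cv_splits", "label_levels", "train_label_levels",
    "test_label_levels", "site_ids", "repeats_per_split",
}
_CV_KEYS = {"num_resample_runs", "run_TCD", "num_parallel_workers"}


def _reject_unknown(mapping: dict, allowed: set, path: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        where = [f"{path}.{k}" if path else k for k in unknown]
        raise ConfigError(
            f"unknown configuration key(s): {where}; "
            f"allowed under {path or '<top level>'}: {sorted(allowed)}")


def build_spec_from_config(config: dict,
                           seed_override: Optional[int] = None,
                           workers_override: Optional[int] = None,
                           ) -> CrossValidatorSpec:
    """Validate a config mapping and build the cross-validator spec.

    ``datasource.site_ids`` may be a list of site IDs or the string
    ``"auto-k"``, which selects all sites with at least
    num_cv_splits × repeats_per_split repetitions of every required level.
    """
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    _reject_unknown(config, TOP_LEVEL_KEYS, "")
    for required in ("binned", "datasource"):
        if required not in config:
            raise ConfigError(f"configuration is missing the {required!r} key")

    ds_cfg = dict(config["datasource"])
    _reject_unknown(ds_cfg, _DS_KEYS, "datasource")
    for required in ("label", "num_cv_splits"):
        if required not in ds_cfg:
            raise ConfigError(f"datasource is missing {required!r}")

    seed = seed_override if seed_override is not None else config.get("seed", 0)
    ds_type = ds_cfg.get("type", "basic")
    if ds_type not in ("basic", "generalization"):
        raise ConfigError(
            f"datasource.type must be 'basic' or 'generalization', "
            f"got {ds_type!r}")

    repeats = ds_cfg.get("repeats_per_split", 1)
    site_ids = ds_cfg.get("site_ids")
    if site_ids == "auto-k":
        from .label_info import get_siteIDs_with_k_label_repetitions
        if ds_type == "generalization":
            levels = sorted(set(ds_cfg.get("train_label_levels", []))
                            | set(ds_cfg.get("test_label_levels", [])))
        else:
            levels = ds_cfg.get("label_levels")
        site_ids = get_siteIDs_with_k_label_repetitions(
            config["binned"], ds_cfg["label"],
            k=ds_cfg["num_cv_splits"] * repeats, levels=levels)
        if not site_ids:
            raise ConfigError(
                "site_ids: auto-k selected zero usable sites; lower "
                "num_cv_splits or collect more repetitions")

    common = dict(
        binned=config["binned"], label=ds_cfg["label"],
        num_cv_splits=ds_cfg["num_cv_splits"], site_ids=site_ids,
        num_label_repeats_per_cv_split=repeats, seed=seed)
    if ds_type == "generalization":
        for required in ("train_label_levels", "test_label_levels"):
            if required not in ds_cfg:
                raise ConfigError(
                    f"generalization datasource is missing {required!r}")
        ds = DataSourceSpec(
            train_label_levels=list(ds_cfg["train_label_levels"]),
            test_label_levels=list(ds_cfg["test_label_levels"]), **common)
    else:
        levels = ds_cfg.get("label_levels")
        ds = DataSourceSpec(
            label_levels=None if levels is None else list(levels), **common)

    cv_cfg = dict(config.get("cross_validator", {}))
    _reject_unknown(cv_cfg, _CV_KEYS, "cross_validator")

    metrics = list(config.get("metrics", ["main_results"]))
    for m in metrics:
        if m not in VALID_METRICS:
            raise ConfigError(
                f"metrics entry {m!r} is not one of {VALID_METRICS}")

    workers = (workers_override if workers_override is not None
               else cv_cfg.get("num_parallel_workers"))
    return CrossValidatorSpec(
        datasource=ds,
        classifier=dict(config.get("classifier", {"type": "max_correlation"})),
        preprocessors=[dict(p) for p in config.get("preprocessors", [])],
        metrics=metrics,
        num_resample_runs=cv_cfg.get("num_resample_runs", 50),
        run_TCD=cv_cfg.get("run_TCD", True),
        num_parallel_workers=workers,
        seed=seed)
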