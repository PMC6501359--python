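"""End-to-end bat-longevity analysis from a single configuration.

Stages, in order: longevity quotients from the allometric baseline;
squared-change parsimony reconstruction of LQ and the count of independent
origins of extreme longevity (LQ above a threshold, default 4.2);
phylogenetic-signal table (Pagel's lambda for continuous variables,
Fritz–Purvis D for binaries); all-subsets PGLS model selection with the
hibernation-by-latitude interaction; the same analysis repeated within
hibernators and non-hibernators; and the residual tables for the
residual-longevity plots (log10 longevity against log10 mass + cave use,
and against log10 mass alone).

Every stochastic component (the D statistic only) is governed by the single
config seed; re-running a config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .trees import read_tree, read_traits, add_log_columns, align
from .allometry import DEFAULT_MODEL, filter_reference, fit_allometry, lq_table
from .ancestral import scp_reconstruct, count_extreme_origins
from .signal import estimate_lambda, d_statistic
from .modelsel import dredge, split_analysis, averaged_frame

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_analysis"]

_FLOAT_FMT = "%.10g"

DEFAULT_VARIABLES = [
    "log10_mass", "abs_median_latitude", "hibernation", "cave_use", "diet",
    "progeny_per_year", "log10_aggregation", "dimorphism", "data_source",
]
DEFAULT_INTERACTIONS = ["hibernation:abs_median_latitude"]
CONTINUOUS_VARIABLES = [
    "log10_longevity", "log10_mass", "abs_median_latitude",
    "progeny_per_year", "log10_aggregation", "dimorphism",
]
BINARY_VARIABLES = ["hibernation", "cave_use", "diet", "data_source"]


@dataclass
class AnalysisConfig:
    tree_path: str
    traits_path: str
    out_dir: str
    reference_path: str | None = None          # else the packaged baseline
    lq_threshold: float = 4.2
    response: str = "log10_longevity"
    variables: list = field(default_factory=lambda: list(DEFAULT_VARIABLES))
    interactions: list = field(default_factory=lambda: list(DEFAULT_INTERACTIONS))
    delta_threshold: float = 4.0
    split_variable: str = "hibernation"
    seed: int = 0
    n_permutations: int = 1000
    binary_codings: dict = field(default_factory=dict)  # column -> {label: 0/1}

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, traits: pd.DataFrame) -> None:
        needed = set(self.variables) | {self.response, self.split_variable}
        for term in self.interactions:
            a, b = term.split(":")
            if a not in self.variables or b not in self.variables:
                raise ValueError(f"interaction {term} references unlisted variable")
        missing = sorted(needed - set(traits.columns))
        if missing:
            raise ValueError(f"trait table lacks columns: {missing}")
        for col, coding in self.binary_codings.items():
            if set(coding.values()) != {0, 1}:
                raise ValueError(f"binary coding for {col!r} must cover both levels 0 and 1")


def _apply_codings(traits: pd.DataFrame, codings: dict) -> pd.DataFrame:
    out = traits.copy()
    for col, mapping in codings.items():
        out[col] = out[col].map(mapping)
        if out[col].isna().any():
            raise ValueError(f"column {col!r} has labels outside its declared coding")
    return out


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns a dict of the key result objects.

    Writes under ``config.out_dir``: lq.csv, ancestral.csv, ancestral.nwk,
    origins.txt, signal.csv, models_full.csv, averaged_full.csv,
    models_hibernator.csv / models_nonhibernator.csv and their averaged_*
    tables, residuals_mass_cave.csv, residuals_mass.csv, run_log.txt.
    Any stage failure aborts, names the stage, and removes partial outputs.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    written: list = []
    log_lines: list = []
    stage = "setup"

    def note(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    def write_csv(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(out, name)
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)

    try:
        note(f"batlife {__version__}; seed={config.seed}")
        stage = "load"
        tree = read_tree(config.tree_path)
        traits = read_traits(config.traits_path)
        traits = _apply_codings(traits, config.binary_codings)
        traits = add_log_columns(traits)
        config.validate(traits)
        note(f"tree: {tree.n_tips} tips; traits: {len(traits)} species")

        stage = "allometry"
        if config.reference_path:
            ref = filter_reference(pd.read_csv(config.reference_path))
            model = fit_allometry(ref)
        else:
            model = DEFAULT_MODEL
        note(f"allometric baseline: a={model.intercept} b={model.slope} n={model.n_reference}")

        stage = "longevity quotients"
        tree_lq, traits_lq = align(tree, traits, ["longevity_years", "body_mass_g"])
        lq = lq_table(traits_lq, model)
        write_csv(lq, "lq.csv")

        stage = "ancestral reconstruction"
        safe_tree = tree_lq.with_min_terminal_length()
        recon = scp_reconstruct(safe_tree, dict(zip(lq["species"], lq["LQ"])),
                                weighted=True)
        write_csv(recon.to_frame(), "ancestral.csv")
        path = os.path.join(out, "ancestral.nwk")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(recon.to_newick() + "\n")
        written.append(path)
        n_origins, roots = count_extreme_origins(recon, config.lq_threshold)
        path = os.path.join(out, "origins.txt")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"threshold LQ > {config.lq_threshold}\n")
            fh.write(f"independent origins: {n_origins}\n")
            for r in roots:
                fh.write(f"lineage root: {r}\n")
        written.append(path)
        note(f"root LQ {recon.ancestral_state:.4f}; {n_origins} origins above {config.lq_threshold}")

        stage = "phylogenetic signal"
        rows = []
        for v in CONTINUOUS_VARIABLES:
            if v not in traits.columns:
                continue
            t_v, tab_v = align(tree, traits, [v])
            est = estimate_lambda(t_v.with_min_terminal_length(),
                                  dict(zip(tab_v["species"], tab_v[v])))
            rows.append({"variable": v, "type": "continuous", "statistic": "lambda",
                        "value": est.lambda_hat, "n_species": t_v.n_tips})
        for i, v in enumerate(BINARY_VARIABLES):
            if v not in traits.columns:
                continue
            t_v, tab_v = align(tree, traits, [v])
            res = d_statistic(t_v.with_min_terminal_length(),
                              dict(zip(tab_v["species"], tab_v[v])),
                              n_permutations=config.n_permutations,
                              seed=config.seed + i)
            rows.append({"variable": v, "type": "binary", "statistic": "D",
                        "value": res.D, "n_species": t_v.n_tips})
        signal_df = pd.DataFrame(rows)
        write_csv(signal_df, "signal.csv")

        stage = "full model selection"
        allvars = [config.response] + list(config.variables)
        tree_m, traits_m = align(tree, traits, allvars)
        tree_m = tree_m.with_min_terminal_length()
        mset, avg = dredge(tree_m, traits_m, config.response, config.variables,
                           config.interactions, config.delta_threshold)
        write_csv(mset.to_frame(), "models_full.csv")
        write_csv(averaged_frame(avg), "averaged_full.csv")
        note(f"full dredge: {len(mset.records)} models, "
             f"{len(mset.candidates)} within {config.delta_threshold} AICc; "
             f"best R2 {mset.records[0].fit.r_squared:.3f}")

        stage = "split analysis"
        split_vars = [v for v in config.variables if v != config.split_variable]
        split = split_analysis(
            tree_m, traits_m, config.response, config.split_variable,
            variables_by_level={0: split_vars, 1: split_vars},
            delta_threshold=config.delta_threshold,
        )
        names = {1: "hibernator", 0: "nonhibernator"}
        for level, (ms, av, n_sp) in split.items():
            write_csv(ms.to_frame(), f"models_{names[level]}.csv")
            write_csv(averaged_frame(av), f"averaged_{names[level]}.csv")
            note(f"{names[level]}: {n_sp} species, {len(ms.candidates)} candidate models, "
                 f"best R2 {ms.records[0].fit.r_squared:.3f}")

        stage = "residual tables"
        from .pgls import pgls_fit, pgls_residuals
        fit_mc = pgls_fit(tree_m, traits_m, config.response,
                          ["log10_mass", "cave_use"])
        res_mc = pgls_residuals(fit_mc)
        res_mc[config.split_variable] = traits_m[config.split_variable].to_numpy()
        write_csv(res_mc, "residuals_mass_cave.csv")
        fit_m = pgls_fit(tree_m, traits_m, config.response, ["log10_mass"])
        res_m = pgls_residuals(fit_m)
        res_m[config.split_variable] = traits_m[config.split_variable].to_numpy()
        write_csv(res_m, "residuals_mass.csv")

        stage = "run log"
        path = os.path.join(out, "run_log.txt")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(log_lines) + "\n")
        written.append(path)
    except Exception as e:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise RuntimeError(f"analysis failed at stage {stage!r}: {e}") from e

    return {"lq": lq, "reconstruction": recon, "n_origins": n_origins,
            "origin_roots": roots, "signal": signal_df,
            "full": (mset, avg), "split": split,
            "residuals_mass_cave": res_mc, "residuals_mass": res_m,
            "allometric_model": model}
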