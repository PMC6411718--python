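"""End-to-end orchestration: raw measurements -> traits -> signal -> PGLS -> report.

`run_full_analysis` wires the stages together: replicate aggregation and
derived traits, trait/tree alignment, Pagel's λ and Blomberg's K (with the
permutation test), one PGLS per binary trait, the disc-vs-adult
correlation, and the allometry/multiple-regression size checks.  Every
number in the report is regenerable from the inputs and the echoed
configuration alone; reports are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparative import BlombergK, PagelLambda, PGLS
from .morphometrics import (
    allometry_fit,
    build_species_table,
    multiple_regression,
    read_sensilla_csv,
    read_specimens_csv,
    trait_correlation,
    write_species_table_csv,
)
from .phylo import align_traits_to_tree, read_newick

__all__ = ["AnalysisConfig", "ReportBundle", "run_full_analysis", "write_report",
           "read_config_file"]

logger = logging.getLogger(__name__)

BINARY_TRAITS = ["wing_pigmentation_female", "wing_pigmentation_male", "light_courtship"]


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs; echoed verbatim into the report."""

    tree_path: str
    specimens_path: str
    sensilla_path: str | None = None
    traits_path: str | None = None          # per-species binary trait CSV
    discs_path: str | None = None
    trait_column: str = "ef_ratio"
    binary_predictors: tuple = tuple(BINARY_TRAITS)
    n_perm: int = 999
    seed: int = 0
    pgls_mode: str = "ml_lambda"
    eye_radius_rule: str = "width-and-half-height"
    out_dir: str = "results"

    def validate(self) -> None:
        for name in ("tree_path", "specimens_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        for name in ("sensilla_path", "traits_path", "discs_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def to_dict(self) -> dict:
        return {
            "tree_path": self.tree_path, "specimens_path": self.specimens_path,
            "sensilla_path": self.sensilla_path, "traits_path": self.traits_path,
            "discs_path": self.discs_path, "trait_column": self.trait_column,
            "binary_predictors": list(self.binary_predictors),
            "n_perm": self.n_perm, "seed": self.seed, "pgls_mode": self.pgls_mode,
            "eye_radius_rule": self.eye_radius_rule, "out_dir": self.out_dir,
        }


def read_config_file(path) -> dict:
    """Flat key = value config file mirroring the CLI flags."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        values[key.replace("-", "_")] = value
    return values


@dataclass
class ReportBundle:
    """All pipeline outputs plus a provenance block."""

    species_table: pd.DataFrame
    lambda_fit: dict
    k_result: dict
    pgls: dict = field(default_factory=dict)           # per binary trait
    disc_correlation: dict | None = None
    allometry: dict = field(default_factory=dict)
    regression: dict | None = None
    alignment: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "species_table": self.species_table.to_dict(orient="list"),
            "lambda": self.lambda_fit,
            "blomberg_k": self.k_result,
            "pgls": self.pgls,
            "allometry": self.allometry,
            "alignment": self.alignment,
            "provenance": self.provenance,
        }
        if self.disc_correlation is not None:
            d["disc_correlation"] = self.disc_correlation
        if self.regression is not None:
            d["multiple_regression"] = self.regression
        return d


def _round_sig(obj, digits: int = 6):
    """Round every float to `digits` significant digits, recursively."""
    if isinstance(obj, dict):
        return {k: _round_sig(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_sig(v, digits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if not math.isfinite(x) or x == 0.0:
            return x
        return float(f"{x:.{digits}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _holm(pvals: dict) -> dict:
    """Holm step-down adjustment across the PGLS analyses."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj, prev = {}, 0.0
    for i, (name, p) in enumerate(items):
        prev = max(prev, min(1.0, (m - i) * p))
        adj[name] = prev
    return {k: adj[k] for k in pvals}


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute every analysis stage the inputs support."""
    config.validate()
    logger.info("reading tree %s", config.tree_path)
    tree = read_newick(Path(config.tree_path).read_text())

    specimens = read_specimens_csv(config.specimens_path)
    logger.info("specimens: %d rows", len(specimens))
    counts = read_sensilla_csv(config.sensilla_path) if config.sensilla_path else ()
    binary_table = None
    if config.traits_path:
        binary_table = pd.read_csv(config.traits_path).set_index("species")
    table = build_species_table(specimens, counts, binary_table,
                                eye_rule=config.eye_radius_rule)
    logger.info("species table: %d species", len(table))

    trait = table.set_index("species")[config.trait_column]
    pruned, aligned, report = align_traits_to_tree(trait, tree)
    logger.info("alignment: %s", report)

    lam = PagelLambda(aligned, pruned).fit()
    k = BlombergK(aligned, pruned).fit(n_perm=config.n_perm, seed=config.seed)

    pgls_block: dict = {}
    raw_p: dict = {}
    if binary_table is not None:
        for name in config.binary_predictors:
            if name not in binary_table.columns:
                continue
            try:
                res = PGLS.from_dataframe(
                    table, config.trait_column, [name], tree, mode=config.pgls_mode).fit()
            except Exception as exc:
                logger.warning("PGLS for %s failed: %s", name, exc)
                continue
            pgls_block[name] = res.to_dict()
            raw_p[name] = res.pvalues[name]
    if raw_p:
        adjusted = _holm(raw_p)
        for name in pgls_block:
            pgls_block[name]["p_holm_adjusted"] = adjusted[name]

    disc_corr = None
    if config.discs_path:
        discs = pd.read_csv(config.discs_path)
        ratios = (discs.assign(ratio=discs.eye_portion_area / discs.antennal_portion_area)
                  .groupby("species")["ratio"].mean())
        merged = pd.concat([ratios.rename("disc_ratio"), trait], axis=1, join="inner").dropna()
        if len(merged) >= 3:
            r, p = trait_correlation(np.log(merged["disc_ratio"]),
                                     np.log(merged[config.trait_column]))
            disc_corr = {"pearson_r": r, "p_value": p, "n": int(len(merged)),
                         "scale": "log-log"}

    # size-scaling checks on species means of the raw measurements
    spec_df = pd.read_csv(config.specimens_path)
    means = spec_df.groupby("species").mean(numeric_only=True)
    merged = table.set_index("species").join(means, how="inner")
    allom = {}
    for trait_col, size_col, slope in [
        ("eye_area", "head_width", 2.0), ("funiculus_area", "head_width", 2.0),
        ("eye_area", "body_length", 2.0), ("funiculus_area", "body_length", 2.0),
        ("ef_ratio", "body_length", 0.0),
    ]:
        fit = allometry_fit(merged[size_col].to_numpy(), merged[trait_col].to_numpy(), slope)
        allom[f"{trait_col}_vs_{size_col}"] = {
            "slope": fit.slope, "intercept": fit.intercept,
            "ci_low": fit.ci_low, "ci_high": fit.ci_high,
            "expected_slope": fit.expected_slope, "p_isometry": fit.p_isometry,
            "n": fit.n, "r_squared": fit.r_squared,
        }
    mreg = multiple_regression(
        np.log(merged["ef_ratio"].to_numpy()),
        pd.DataFrame({"log_body_length": np.log(merged["body_length"]),
                      "log_head_width": np.log(merged["head_width"])}).reset_index(drop=True),
    )
    regression = {
        "response": "log_ef_ratio",
        "coefficients": {k: float(v) for k, v in mreg.params.items()},
        "standard_errors": {k: float(v) for k, v in mreg.bse.items()},
        "t_values": {k: float(v) for k, v in mreg.tvalues.items()},
        "p_values": {k: float(v) for k, v in mreg.pvalues.items()},
        "df": int(mreg.df_resid),
    }

    return ReportBundle(
        species_table=table,
        lambda_fit=lam.to_dict(),
        k_result=k.to_dict(),
        pgls=pgls_block,
        disc_correlation=disc_corr,
        allometry=allom,
        regression=regression,
        alignment={
            "n_aligned": len(report.kept),
            "dropped_from_tree": list(report.dropped_from_tree),
            "dropped_from_table": list(report.dropped_from_table),
        },
        provenance={
            "package": "sensetrade",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
        },
    )


def _markdown(payload: dict) -> str:
    lines = ["# Sensory-allocation comparative analysis", ""]
    lam = payload["lambda"]
    k = payload["blomberg_k"]
    lines += [
        "## Phylogenetic signal",
        "",
        f"- Pagel's lambda = {lam['lambda']} (sigma2 = {lam['sigma2']}, "
        f"loglik = {lam['loglik']}; p vs 0 = {lam['p_vs_zero']}, "
        f"p vs 1 = {lam['p_vs_one']})",
        f"- Blomberg's K = {k['k']} (permutation p = {k.get('p_perm')}, "
        f"{k.get('n_perm')} permutations, seed {k.get('seed')})",
        "",
    ]
    if payload.get("pgls"):
        lines += ["## PGLS (response: EF ratio)", ""]
        for name, res in payload["pgls"].items():
            coef = res["coefficients"].get(name)
            p = res["p_values"].get(name)
            lines.append(f"- {name}: coef = {coef}, p = {p} "
                         f"(Holm-adjusted p = {res.get('p_holm_adjusted')}, "
                         f"lambda = {res['lambda_used']}, mode = {res['correlation_mode']})")
        lines.append("")
    if "disc_correlation" in payload:
        d = payload["disc_correlation"]
        lines += ["## Imaginal disc vs adult EF ratio", "",
                  f"- Pearson r = {d['pearson_r']} (p = {d['p_value']}, "
                  f"n = {d['n']}, {d['scale']})", ""]
    lines += ["## Allometry (log-log OLS)", ""]
    for name, fit in payload["allometry"].items():
        lines.append(
            f"- {name}: slope = {fit['slope']} "
            f"[{fit['ci_low']}, {fit['ci_high']}], expected {fit['expected_slope']}, "
            f"p(slope = expected) = {fit['p_isometry']}")
    lines.append("")
    if "multiple_regression" in payload:
        m = payload["multiple_regression"]
        lines += ["## Multiple regression (response: log EF ratio)", ""]
        for term, coef in m["coefficients"].items():
            lines.append(f"- {term}: coef = {coef}, p = {m['p_values'][term]}")
        lines.append("")
    a = payload["alignment"]
    prov = payload["provenance"]
    lines += [
        "## Provenance",
        "",
        f"- {a['n_aligned']} species aligned to the tree; "
        f"pruned from tree: {a['dropped_from_tree'] or 'none'}; "
        f"unused table rows: {a['dropped_from_table'] or 'none'}",
        f"- sensetrade {prov['version']}, seed {prov['seed']}",
        f"- eye radius rule: {prov['config']['eye_radius_rule']}; "
        f"PGLS mode: {prov['config']['pgls_mode']}; "
        f"permutations: {prov['config']['n_perm']}",
        "",
    ]
    return "\n".join(lines)


def write_report(bundle: ReportBundle, out_dir, formats=("json", "markdown")) -> dict:
    """Serialize the bundle; floats at 6 significant digits, stable key order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = _round_sig(bundle.to_dict())
    written = {}
    if "json" in formats:
        path = out / "report.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written["json"] = str(path)
    if "markdown" in formats:
        path = out / "report.md"
        path.write_text(_markdown(payload))
        written["markdown"] = str(path)
    table_path = out / "species_table.csv"
    write_species_table_csv(bundle.species_table, table_path)
    written["species_table"] = str(table_path)
    return written
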