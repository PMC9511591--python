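"""End-to-end orchestration: descriptives -> Stage 1 -> gated Stage 2 -> reports.

``run_pipeline`` mirrors the analysis flow of the study: descriptive
summaries, the 21-row random-family analysis, and variance-component
heritability estimation run only for traits with at least one significant
generation pairing (p < alpha).  All outputs are deterministic given the
configuration and seed, and a JSON manifest records enough provenance to
reproduce them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .pedigree import Pedigree, RelatednessMatrix, build_pedigree, grm
from .stage1 import Stage1Result, adjust_pvalues, run_stage1, write_stage1_tsv
from .stage2 import (
    PriorSpec,
    VarianceComponents,
    gibbs_fit,
    hmc_fit,
    make_lmm_spec,
    reml_fit,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "descriptives", "write_stage2_tsv"]


@dataclass
class RunConfig:
    """Configuration of a full two-stage run."""

    n_resamples: int = 5000
    alpha: float = 0.05
    methods: tuple[str, ...] = ("reml", "mcmc", "hmc")
    n_iter: int = 100_000
    burn_in: int = 10_000
    seed: int = 0
    priors: PriorSpec = field(default_factory=PriorSpec)
    keep_null_draws: bool = False
    # optional sensitivity layer; the standard analysis reports unadjusted p
    multiplicity: str | None = None  # None | "bonferroni" | "bh"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if self.multiplicity not in (None, "bonferroni", "bh"):
            raise ValueError(f"unknown multiplicity method {self.multiplicity!r}")
        bad = set(self.methods) - {"reml", "mcmc", "hmc"}
        if bad:
            raise ValueError(f"unknown stage-2 methods: {sorted(bad)}")


@dataclass
class RunReport:
    descriptives: pd.DataFrame
    stage1: list[Stage1Result]
    stage2: dict[str, dict[str, VarianceComponents]]  # trait -> method -> components
    selected_traits: tuple[str, ...]
    manifest: dict


def descriptives(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-generation descriptive summary: median (IQR) and n, n (%) flags."""
    rows = []
    continuous = [
        "age", "height", "weight", "waist", "muac",
        "brachial_sbp", "brachial_dbp", "resting_hr",
        "central_sbp", "central_dbp", "pulse_pressure", "mean_arterial_pressure",
        "pwv", "cimt_left", "lvmi_bsa",
    ]
    flags = ["on_antihypertensives", "tobacco_user"]
    for gen in ("grandparent", "parent", "child"):
        sub = dataset[dataset["generation"] == gen]
        n_gen = len(sub)
        for var in continuous:
            if var not in sub.columns:
                continue
            v = pd.to_numeric(sub[var], errors="coerce").dropna()
            if v.empty:
                continue
            rows.append(
                {
                    "generation": gen,
                    "variable": var,
                    "n": int(v.size),
                    "median": float(v.median()),
                    "iqr": float(v.quantile(0.75) - v.quantile(0.25)),
                    "count": np.nan,
                    "percent": np.nan,
                }
            )
        rows.append(
            {
                "generation": gen,
                "variable": "female",
                "n": n_gen,
                "median": np.nan,
                "iqr": np.nan,
                "count": int((sub["sex"] == "female").sum()),
                "percent": 100.0 * float((sub["sex"] == "female").mean()) if n_gen else np.nan,
            }
        )
        for var in flags:
            if var not in sub.columns:
                continue
            v = sub[var].dropna()
            if v.empty:
                continue
            rows.append(
                {
                    "generation": gen,
                    "variable": var,
                    "n": int(v.size),
                    "median": np.nan,
                    "iqr": np.nan,
                    "count": int(v.astype(bool).sum()),
                    "percent": 100.0 * float(v.astype(bool).mean()),
                }
            )
    return pd.DataFrame(rows)


def _fit_stage2_trait(
    dataset: pd.DataFrame,
    relatedness: RelatednessMatrix,
    trait: str,
    config: RunConfig,
    seed: np.random.SeedSequence,
) -> dict[str, VarianceComponents]:
    spec = make_lmm_spec(dataset, relatedness, trait)
    out: dict[str, VarianceComponents] = {}
    streams = dict(zip(("mcmc", "hmc"), seed.spawn(2)))
    for method in config.methods:
        if method == "reml":
            out["reml"] = reml_fit(spec)
        elif method == "mcmc":
            out["mcmc"] = gibbs_fit(
                spec, config.priors, config.n_iter, config.burn_in, streams["mcmc"]
            ).summarize()
        elif method == "hmc":
            out["hmc"] = hmc_fit(
                spec, config.priors, config.n_iter, config.burn_in, streams["hmc"]
            ).summarize()
    return out


def run_pipeline(
    dataset: pd.DataFrame,
    pedigree: Pedigree | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Run descriptives, Stage 1 over the full trait registry, and Stage 2
    for every trait with at least one pairing significant at alpha.

    The pedigree defaults to the one implied by the dataset's mother links.
    With ``out_dir`` set, writes table1/table2/table3-style TSVs and a JSON
    manifest.
    """
    config = config or RunConfig()
    if pedigree is None:
        pedigree = build_pedigree(dataset)
    relatedness = grm(pedigree)

    desc = descriptives(dataset)
    root = np.random.SeedSequence(config.seed)
    s1_seed, s2_root = root.spawn(2)
    stage1_results = run_stage1(
        dataset,
        n_resamples=config.n_resamples,
        seed=s1_seed,
        keep_null=config.keep_null_draws,
    )

    # Stage 2 gate: any pairing significant for the trait
    selected: list[str] = []
    for r in stage1_results:
        if r.p is not None and r.p < config.alpha and r.spec.trait_name not in selected:
            selected.append(r.spec.trait_name)

    stage2_results: dict[str, dict[str, VarianceComponents]] = {}
    trait_seeds = s2_root.spawn(max(len(selected), 1))
    failures: dict[str, str] = {}
    for trait, ss in zip(selected, trait_seeds):
        try:
            stage2_results[trait] = _fit_stage2_trait(
                dataset, relatedness, trait, config, ss
            )
        except (ValueError, RuntimeError) as e:  # isolate per-trait failures
            failures[trait] = str(e)

    manifest = {
        "package_version": _pkg_version,
        "config": {
            "n_resamples": config.n_resamples,
            "alpha": config.alpha,
            "methods": list(config.methods),
            "n_iter": config.n_iter,
            "burn_in": config.burn_in,
            "seed": config.seed,
            "multiplicity": config.multiplicity,
            "priors": {
                "beta_sd": config.priors.beta_sd,
                "s1": config.priors.s1,
                "s2": config.priors.s2,
            },
        },
        "n_individuals": int(len(dataset)),
        "n_families": int(dataset["family_id"].nunique()),
        "dataset_sha256": hashlib.sha256(
            dataset.to_csv(index=False).encode()
        ).hexdigest(),
        "selected_traits": selected,
        "stage2_failures": failures,
    }

    report = RunReport(
        descriptives=desc,
        stage1=stage1_results,
        stage2=stage2_results,
        selected_traits=tuple(selected),
        manifest=manifest,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        desc.to_csv(out / "table1_descriptives.tsv", sep="\t", index=False)
        adjusted = (
            adjust_pvalues(stage1_results, config.multiplicity)
            if config.multiplicity
            else None
        )
        write_stage1_tsv(stage1_results, out / "table2_stage1.tsv", adjusted=adjusted)
        write_stage2_tsv(stage2_results, out / "table3_stage2.tsv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


_METHOD_LABEL = {"reml": "ReML", "mcmc": "MCMC", "hmc": "HMC"}


def _cell(est: float | None, sd: float | None) -> str:
    if est is None:
        return ""
    return f"{est:.3f} ({sd:.3f})" if sd is not None else f"{est:.3f} (–)"


def write_stage2_tsv(
    stage2: dict[str, dict[str, VarianceComponents]], path: str | Path
) -> None:
    """Write the Stage 2 report: one column per trait x method, rows for the
    polygenic/error/phenotypic variances, heritability and the age effect."""
    cols: dict[str, dict[str, str]] = {}
    for trait, methods in stage2.items():
        for method, vc in methods.items():
            label = f"{trait} {_METHOD_LABEL.get(method, method)}"
            beta_age = vc.beta[1] if vc.beta is not None and len(vc.beta) > 1 else None
            beta_age_sd = (
                vc.beta_sd[1] if vc.beta_sd is not None and len(vc.beta_sd) > 1 else None
            )
            cols[label] = {
                "Polygenic variance": _cell(vc.sigma_g2, vc.sigma_g2_sd),
                "Error variance": _cell(vc.sigma_e2, vc.sigma_e2_sd),
                "Phenotypic variance": _cell(vc.phenotypic, vc.phenotypic_sd),
                "Heritability (h2)": _cell(vc.h2, vc.h2_sd),
                "Beta (age)": _cell(beta_age, beta_age_sd),
            }
    df = pd.DataFrame(cols)
    df.index.name = "Estimate"
    df.to_csv(path, sep="\t")
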