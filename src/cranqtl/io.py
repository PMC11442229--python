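"""Configuration, seeds, CSV interchange, and the end-to-end pipeline driver.

Every interchange table is a plain CSV with a fixed, validated header so
that hand-transcribed cross-study QTL tables drop straight into the
meta-QTL stage. One master seed deterministically derives a sub-seed per
stochastic stage, so a rerun of the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2

from cranqtl import __version__
from cranqtl.meta import MetaQtl, TraitGroup, meta_table
from cranqtl.qtl import QtlHit

QTL_COLUMNS = ["trait", "population", "study", "model", "method",
               "linkage_group", "position", "lod", "marker_r2", "lo", "hi",
               "effect_maternal", "effect_paternal", "effect_interaction"]

PHENO_COLUMNS = ["genotype", "year", "row", "col", "upright", "trait", "value"]


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2^31 from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _check_header(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing mandatory columns: {missing}")


def write_map(lmap: pd.DataFrame, path) -> None:
    lmap.to_csv(path, index=False)


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, ["marker_id", "linkage_group", "position"], "linkage map")
    return df


def write_genotypes(geno: pd.DataFrame, path) -> None:
    geno.to_csv(path, index=True, index_label="progeny_id")


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, ["progeny_id"], "genotype table")
    return df.set_index("progeny_id")


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, PHENO_COLUMNS, "phenotype table")
    return df


def write_qtl_table(hits: list[QtlHit] | pd.DataFrame, path) -> None:
    if not isinstance(hits, pd.DataFrame):
        from cranqtl.qtl import hits_to_frame
        hits = hits_to_frame(hits)
    # %.17g keeps doubles exact so read(write(x)) round-trips bitwise
    hits.to_csv(path, index=False, float_format="%.17g")


def read_qtl_table(path) -> list[QtlHit]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_header(df, QTL_COLUMNS, "QTL table")
    hits = []
    for _, r in df.iterrows():
        hits.append(QtlHit(
            trait=str(r["trait"]), population=str(r["population"]),
            study=str(r["study"]), model=str(r["model"]), method=str(r["method"]),
            linkage_group=int(r["linkage_group"]), position=float(r["position"]),
            lod=float(r["lod"]), marker_r2=float(r["marker_r2"]),
            lo=float(r["lo"]), hi=float(r["hi"]),
            effect_maternal=float(r["effect_maternal"]),
            effect_paternal=float(r["effect_paternal"]),
            effect_interaction=float(r["effect_interaction"])))
    return hits


def write_meta_table(metas: list[MetaQtl], path) -> None:
    meta_table(metas).to_csv(path, index=False)


def read_groups(path) -> list[TraitGroup]:
    """Trait-group config: YAML list of {group_id, traits, populations, studies, filters}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups = []
    for item in raw:
        filters = [(f["statistic"], f["comparator"], float(f["value"]))
                   for f in item.get("filters", [])]
        groups.append(TraitGroup(group_id=item["group_id"],
                                 traits=list(item["traits"]),
                                 populations=list(item.get("populations", [])),
                                 studies=list(item.get("studies", [])),
                                 filters=filters))
    return groups


# ---------------------------------------------------------------------------
# run configuration

_DEFAULTS = {
    "simulate": {"n_lg": 5, "markers_per_lg": 11, "length_cm": 100.0,
                 "n_progeny": 100, "years": [2011, 2012, 2013],
                 "uprights_per_genotype": 10, "n_field_cols": 10,
                 "traits": {}},
    "prep": {"alpha": 0.05, "sd_cut": 3.0, "cut_height": 0.6},
    "blup": {"spline_knots": [4, 4], "optional_terms": ["row", "col", "spline"]},
    "scan": {"step": 2.0, "n_perm": 300, "percentile": 80.0,
             "stepwise": False, "stepwise_percentile": 95.0},
    "metaqtl": {"min_models": 3, "min_r2": 0.10},
}


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    population: str = "SIM01"
    study: str = "this_study"
    stages: dict = dfield(default_factory=dict)

    def stage(self, name: str) -> dict:
        merged = dict(_DEFAULTS.get(name, {}))
        merged.update(self.stages.get(name, {}))
        return merged


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError("config must set an explicit master seed")
    outdir = Path(raw.get("outdir", "cranqtl_out"))
    stages = {k: v for k, v in raw.items()
              if k in _DEFAULTS and isinstance(v, dict)}
    return RunConfig(seed=int(raw["seed"]), outdir=outdir,
                     population=raw.get("population", "SIM01"),
                     study=raw.get("study", "this_study"), stages=stages)


def _arch_from_dict(d: dict):
    from cranqtl.simulate import QtlEffect, TraitArchitecture

    qtl = [QtlEffect(int(q["linkage_group"]), float(q["position"]),
                     float(q.get("maternal", 0.0)), float(q.get("paternal", 0.0)),
                     float(q.get("interaction", 0.0)))
           for q in d.get("qtl", [])]
    return TraitArchitecture(
        qtl=qtl, mu=float(d.get("mu", 0.0)),
        polygenic_variance=float(d.get("polygenic_variance", 0.0)),
        gxy_variance=float(d.get("gxy_variance", 0.0)),
        residual_variance=float(d.get("residual_variance", 1.0)),
        spatial_amplitude=float(d.get("spatial_amplitude", 0.0)),
        row_variance=float(d.get("row_variance", 0.0)),
        col_variance=float(d.get("col_variance", 0.0)))


def dosages_from_classes(geno: pd.DataFrame) -> pd.DataFrame:
    """Biallelic 0/1/2 dosages from four-way classes (A and C count as reference)."""
    vals = geno.to_numpy().astype(str)
    dos = (np.char.startswith(vals, "A").astype(int)
           + np.char.endswith(vals, "C").astype(int))
    return pd.DataFrame(dos, index=geno.index, columns=geno.columns)


def fit_all_models(means: pd.DataFrame, layout: pd.DataFrame,
                   A: pd.DataFrame, bc: dict) -> tuple[list, list, dict]:
    """Fit the within-year models and the across-year model for every trait.

    For each trait and each model (one per year plus "all_years"): AIC
    search over spatial random terms, then for the across-year model a
    boundary-corrected LRT decides whether genotype-by-year stays. Returns
    (variance-component rows, BLUP rows, {(trait, model): BLUP series}).
    """
    from cranqtl import blup as blup_mod

    years = sorted(means["year"].unique())
    vc_rows, blup_rows = [], []
    blups_by_model: dict[tuple[str, str], pd.Series] = {}
    lay = layout.rename(columns={"progeny_id": "genotype"})
    for trait in sorted(means["trait"].unique()):
        sub_all = means[means["trait"] == trait].merge(lay, on="genotype")
        models = [(str(y), sub_all[sub_all["year"] == y]) for y in years]
        models.append(("all_years", sub_all))
        for label, sub in models:
            across = label == "all_years"
            y = sub["value"].to_numpy(dtype=float)
            X, _ = blup_mod.fixed_design(sub, year_fixed=across)
            subset, vc, blup, terms, _tab = blup_mod.select_model_aic(
                y, X, sub, A=A, gxy=False,
                optional=tuple(bc["optional_terms"]),
                spline_knots=tuple(bc["spline_knots"]))
            if across:
                terms_ge = blup_mod.build_terms(
                    sub, A=A, include=subset, gxy=True,
                    spline_knots=tuple(bc["spline_knots"]))
                vc_ge, blup_ge = blup_mod.fit_reml(y, X, terms_ge)
                keep, _stat, _p = blup_mod.gate_gxy(vc_ge, vc)
                if keep:
                    vc, blup = vc_ge, blup_ge
            # genotype-effect significance gate: QTL are only scanned for
            # models whose genotype variance is supported by the data
            # (boundary-corrected LRT against the same model minus genotype)
            null_terms = blup_mod.build_terms(
                sub, A=A, include=subset, gxy="gxy" in vc.components,
                spline_knots=tuple(bc["spline_knots"]))
            null_terms = [t for t in null_terms if t.name != "genotype"]
            vc_null, _ = blup_mod.fit_reml(y, X, null_terms)
            g_stat = max(2.0 * (vc.loglik - vc_null.loglik), 0.0)
            g_p = 0.5 * chi2.sf(g_stat, df=1) if g_stat > 0 else 1.0
            h2 = blup_mod.heritability(vc, across_year=across,
                                       n_years=len(years) if across else None)
            vc_rows.append({"trait": trait, "model": label,
                            **{f"sigma2_{k}": v for k, v in vc.components.items()},
                            "sigma2_residual": vc.residual, "h2": h2,
                            "genotype_p": float(g_p),
                            "aic": vc.aic, "loglik": vc.loglik,
                            "converged": vc.converged,
                            "terms": "+".join(subset) or "(none)"})
            gb = blup.genotype_blups()
            if g_p < bc.get("genotype_alpha", 0.05):
                blups_by_model[(trait, label)] = gb
            for gid, val in gb.items():
                blup_rows.append({"trait": trait, "model": label,
                                  "genotype": gid, "blup": val})
    return vc_rows, blup_rows, blups_by_model


def scan_all(geno: pd.DataFrame, lmap: pd.DataFrame, blups_by_model: dict,
             qc: dict, seed: int, population: str, study: str) -> list[QtlHit]:
    """Permutation-gated scans (scanone, optionally stepwise) for every trait model."""
    from cranqtl import qtl as qtl_mod

    probs = qtl_mod.calc_genoprob(geno, lmap, step=qc["step"])
    order = {g: i for i, g in enumerate(probs.progeny)}
    hits: list[QtlHit] = []
    for (trait, label), gb in sorted(blups_by_model.items()):
        yv = np.full(len(order), np.nan)
        for gid, val in gb.items():
            if gid in order:
                yv[order[gid]] = val
        yv = np.nan_to_num(yv, nan=float(np.nanmean(yv)))
        thr = qtl_mod.permutation_threshold(
            probs, yv, qc["n_perm"], qc["percentile"],
            derive_seed(seed, f"perm:{trait}:{label}"))
        curve = qtl_mod.scanone_hk(probs, yv)
        if curve["lod"].max() >= thr.threshold:
            hits.append(qtl_mod.scan_to_hit(
                probs, yv, curve, trait=trait, population=population,
                study=study, model=label, method="scanone"))
        if qc["stepwise"]:
            thr95 = qtl_mod.permutation_threshold(
                probs, yv, qc["n_perm"], qc["stepwise_percentile"],
                derive_seed(seed, f"perm95:{trait}:{label}"))
            hits.extend(qtl_mod.stepwise_scan(
                probs, yv, thr95.threshold, trait=trait,
                population=population, study=study, model=label))
    return hits


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate → prep → blup → scan → metaqtl, writing every intermediate.

    Returns the manifest dict (also written as JSON): seeds, versions, row
    counts after every stage and filter, plus the paths of all outputs.
    """
    from cranqtl import simulate as sim
    from cranqtl import prep as prep_mod
    from cranqtl import blup as blup_mod
    from cranqtl import qtl as qtl_mod
    from cranqtl import meta as meta_mod

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": {},
                "outputs": {}}

    # --- simulate -----------------------------------------------------------
    sc = config.stage("simulate")
    if not sc["traits"]:
        raise ValueError("config defines no traits to simulate")
    lmap = sim.simulate_map(sc["n_lg"], sc["markers_per_lg"], sc["length_cm"],
                            derive_seed(config.seed, "map"))
    geno = sim.simulate_cross(lmap, sc["n_progeny"],
                              derive_seed(config.seed, "cross"))
    layout = sim.make_layout(geno.index, sc["n_field_cols"])
    phenos, truths = [], []
    for trait, spec in sorted(sc["traits"].items()):
        ph, tr = sim.simulate_traits(geno, lmap, _arch_from_dict(spec), layout,
                                     sc["years"], sc["uprights_per_genotype"],
                                     derive_seed(config.seed, f"trait:{trait}"),
                                     trait=trait)
        phenos.append(ph)
        tr.insert(0, "trait", trait)
        truths.append(tr)
    pheno = pd.concat(phenos, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    write_map(lmap, out / "map.csv")
    write_genotypes(geno, out / "genotypes.csv")
    write_phenotypes(pheno, out / "phenotypes.csv")
    truth.to_csv(out / "truth.csv", index=False)
    manifest["stages"]["simulate"] = {
        "seed": derive_seed(config.seed, "map"), "n_markers": len(lmap),
        "n_progeny": len(geno), "n_observations": len(pheno)}

    # --- prep ---------------------------------------------------------------
    pc = config.stage("prep")
    clean, log = prep_mod.trim_outliers(pheno, pc["alpha"], pc["sd_cut"])
    means = prep_mod.upright_means(clean)
    clean.to_csv(out / "phenotypes_clean.csv", index=False)
    log.to_csv(out / "removal_log.csv", index=False)
    means.to_csv(out / "upright_means.csv", index=False)
    manifest["stages"]["prep"] = {"n_in": len(pheno), "n_removed": len(log),
                                  "n_out": len(clean), "n_means": len(means)}
    if means["trait"].nunique() >= 3:
        rbar, pvals, clusters, dropped = prep_mod.correlation_cliques(
            means, pc["cut_height"])
        rbar.to_csv(out / "trait_correlations.csv")
        with open(out / "trait_clusters.json", "w") as fh:
            json.dump({str(k): v for k, v in clusters.items()}, fh, indent=2)

    # --- shape chimeras (optional) -----------------------------------------
    shape_cfg = sc.get("shape")
    if shape_cfg:
        from cranqtl.chimera import chimera_table
        from cranqtl.templates import shape_templates

        rng = np.random.default_rng(derive_seed(config.seed, "shape-bias"))
        conc = float(shape_cfg.get("concentration", 2.0))
        bias = rng.dirichlet(np.full(5, conc), size=len(geno))
        scores = sim.simulate_shape_scores(
            len(geno), int(shape_cfg.get("uprights", 10)), bias,
            derive_seed(config.seed, "shape-scores"), years=sc["years"])
        templates = shape_templates(size=int(shape_cfg.get("size", 128)),
                                    target_area=int(shape_cfg.get("area", 3000)))
        desc = chimera_table(scores, templates)
        scores.to_csv(out / "shape_scores.csv", index=False)
        desc.to_csv(out / "chimera_descriptors.csv", index=False)
        # descriptors are genotype-year analysis units: append as traits
        desc_long = desc.melt(id_vars=["genotype", "year"], var_name="trait",
                              value_name="value")
        desc_long["n_uprights"] = 1
        means = pd.concat([means, desc_long], ignore_index=True)
        manifest["stages"]["shape"] = {"n_scores": len(scores),
                                       "n_chimeras": len(desc)}

    # --- blup (per trait, per model) ---------------------------------------
    bc = config.stage("blup")
    A = blup_mod.compute_A(dosages_from_classes(geno))
    vc_rows, blup_rows, blups_by_model = fit_all_models(means, layout, A, bc)
    pd.DataFrame(vc_rows).to_csv(out / "variance_components.csv", index=False)
    pd.DataFrame(blup_rows).to_csv(out / "blups.csv", index=False)
    manifest["stages"]["blup"] = {"n_models_fit": len(vc_rows)}

    # --- scan ---------------------------------------------------------------
    qc = config.stage("scan")
    hits = scan_all(geno, lmap, blups_by_model, qc, config.seed,
                    config.population, config.study)
    write_qtl_table(hits, out / "qtl.csv")
    manifest["stages"]["scan"] = {"n_hits": len(hits)}

    # --- metaqtl ------------------------------------------------------------
    mc = config.stage("metaqtl")
    metas = meta_mod.stability_filter(hits, mc["min_models"], mc["min_r2"])
    write_meta_table(metas, out / "metaqtl.csv")
    manifest["stages"]["metaqtl"] = {"n_meta": len(metas),
                                     "n_hits_in": len(hits)}

    manifest["outputs"] = {p.name: str(p) for p in sorted(out.glob("*.csv"))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
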