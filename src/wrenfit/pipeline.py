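"""End-to-end analysis driver: relatedness -> reproductive values ->
individual fitness -> hurdle-model selection -> summary report.

The pipeline mirrors the field analysis: estimate pairwise relatedness of
genetic-parent and social-pair dyads from the markers, derive f and k,
estimate the life-cycle components and reproductive values from the annual
state records, compute three-year reproductive-value-weighted fitness per
offspring, assemble covariates, and run AICc all-subset selection of the
two-part hurdle model.  A fixed seed makes the whole report reproducible.
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from wrenfit import demography, fitness as fitness_mod, io, relatedness
from wrenfit.inference import (
    ModelSpec,
    all_subset_selection,
    paired_halfsib_table,
    wilcoxon_paired,
)
from wrenfit.simdata import SimConfig, SyntheticDataset, simulate_population

#: default hurdle candidate terms; f linear and the inbred threshold are
#: mutually exclusive forms of the same covariate
DEFAULT_CANDIDATES = ("epp", "inbred", "f", "n_helpers", "year_mean")
DEFAULT_EXCLUSIVE = (("inbred", "f"),)


def relatedness_tables(dataset) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(offspring_f, pairs_k, dyads) estimated from the marker data.

    offspring_f: one row per offspring with the genetic-parent dyad's r and
    f = r/2.  pairs_k: one row per unique social pair with k = r/2.
    """
    gt = dataset.genotypes
    freqs = relatedness.allele_frequencies(gt)
    par = dataset.parentage
    gpairs = par[["genetic_dam", "genetic_sire"]].drop_duplicates()
    gdy = relatedness.dyad_table(gt, list(gpairs.itertuples(index=False, name=None)), freqs)
    gkey = dict(
        zip(zip(gdy["id_i"], gdy["id_j"]), zip(gdy["r"], gdy["f"], gdy["n_loci"]))
    )
    rows = []
    for row in par.itertuples():
        r, f, nl = gkey[(row.genetic_dam, row.genetic_sire)]
        rows.append((row.offspring, r, f, nl, relatedness.classify_close(f) if np.isfinite(f) else False))
    offspring_f = pd.DataFrame(rows, columns=["offspring", "r", "f", "n_loci", "inbred"])
    spairs = par[["social_dam", "social_sire"]].drop_duplicates()
    sdy = relatedness.dyad_table(gt, list(spairs.itertuples(index=False, name=None)), freqs)
    pairs_k = sdy.rename(
        columns={"id_i": "social_dam", "id_j": "social_sire", "f": "k", "close_flag": "close_kin"}
    )
    return offspring_f, pairs_k, gdy


def covariate_table(dataset, offspring_f: pd.DataFrame, pairs_k: pd.DataFrame) -> pd.DataFrame:
    """Per-offspring covariates for the fitness models."""
    par = dataset.parentage
    nests = dataset.nests.set_index("nest")
    yq = fitness_mod.year_quality(dataset.nests)
    yq_mean = dict(zip(yq["year"], yq["mean_fledged"]))
    yq_poor = dict(zip(yq["year"], yq["poor"]))
    cond = fitness_mod.body_condition(dataset.measurements.set_index("id"))
    fmap = offspring_f.set_index("offspring")
    kmap = pairs_k.set_index(["social_dam", "social_sire"])
    sex_of = dict(zip(dataset.individuals["id"], dataset.individuals["sex"]))
    rows = []
    for row in par.itertuples():
        nest = nests.loc[row.nest]
        kk = kmap.loc[(row.social_dam, row.social_sire)]
        rows.append(
            {
                "id": row.offspring,
                "nest": row.nest,
                "mother": row.social_dam,
                "year": row.year,
                "sex": sex_of.get(row.offspring),
                "epp": float(bool(row.epp)),
                "fledged": float(bool(getattr(row, "fledged", True))),
                "f": float(fmap.loc[row.offspring, "f"]),
                "inbred": float(bool(fmap.loc[row.offspring, "inbred"])),
                "k": float(kk["k"]),
                "close_kin_pair": float(bool(kk["close_kin"])),
                "n_helpers": float(nest["helpers_female"] + nest["helpers_male"]),
                "brood_size": float(nest["brood_size"]),
                "year_mean": float(yq_mean[row.year]),
                "poor_year": float(bool(yq_poor[row.year])),
                "condition": float(cond.loc[row.offspring, "condition"]) if row.offspring in cond.index else np.nan,
                "size": float(cond.loc[row.offspring, "size"]) if row.offspring in cond.index else np.nan,
            }
        )
    return pd.DataFrame(rows)


def component_table(dataset, offspring_f: pd.DataFrame, pairs_k: pd.DataFrame) -> pd.DataFrame:
    """Per-offspring fitness-component responses joined to the covariates.

    Adds: survived_1y (fledged birds; alive at the next census),
    survived_adult (alive at age 3, among first-year survivors), recruited
    (dominant by age 3, among those alive then), n_fledged (genetic
    fledglings produced in the first three years, among those alive at 3).
    """
    covs = covariate_table(dataset, offspring_f, pairs_k)
    alive = {(r.id, r.year) for r in dataset.states.itertuples()}
    stage_of = {(r.id, r.year): r.stage for r in dataset.states.itertuples()}
    par = dataset.parentage
    fledged_kids: dict = {}
    for row in par.itertuples():
        if not bool(getattr(row, "fledged", True)):
            continue
        for parent in (row.genetic_dam, row.genetic_sire):
            fledged_kids.setdefault(parent, []).append(row.year)
    year_of = dict(zip(par["offspring"], par["year"]))
    fledged_of = dict(zip(par["offspring"], par["fledged"].astype(bool)))
    out = covs.copy()
    s1, sa, rec, rep = [], [], [], []
    for oid in out["id"]:
        t0 = year_of[oid]
        if not fledged_of[oid]:
            s1.append(np.nan), sa.append(np.nan), rec.append(np.nan), rep.append(np.nan)
            continue
        alive1 = (oid, t0 + 1) in alive
        s1.append(float(alive1))
        alive3 = (oid, t0 + 3) in alive
        sa.append(float(alive3) if alive1 else np.nan)
        if alive3:
            rec.append(float(stage_of.get((oid, t0 + 3)) == "dominant"))
            rep.append(float(sum(1 for y in fledged_kids.get(oid, []) if t0 < y <= t0 + 3)))
        else:
            rec.append(np.nan), rep.append(np.nan)
    out["survived_1y"] = s1
    out["survived_adult"] = sa
    out["recruited"] = rec
    out["n_fledged"] = rep
    return out


def run_pipeline(
    source: SimConfig | SyntheticDataset | io.Dataset,
    out_dir=None,
    candidates=DEFAULT_CANDIDATES,
    exclusive=DEFAULT_EXCLUSIVE,
    seed: int | None = None,
) -> dict:
    """Run the full analysis; returns the report dict (and writes stage
    outputs to ``out_dir`` when given).

    ``source`` may be a simulation config (simulated on the fly), an
    in-memory dataset, or a loaded :class:`wrenfit.io.Dataset`.
    """
    t0 = time.time()
    if isinstance(source, SimConfig):
        if seed is not None:
            source = type(source)(**{**source.__dict__, "seed": seed})
        dataset = simulate_population(source)
    else:
        dataset = source
    if hasattr(dataset, "cohort_ids"):
        cohort_ids = dataset.cohort_ids
    else:
        cohort_ids = list(dataset.parentage["offspring"])

    offspring_f, pairs_k, dyads = relatedness_tables(dataset)
    fledged = set(dataset.parentage.loc[dataset.parentage["fledged"].astype(bool), "offspring"])
    spec = demography.estimate_lifecycle(
        dataset.individuals, dataset.parentage, dataset.states, fledged_ids=fledged
    )
    A = demography.build_projection_matrix(spec)
    rv = demography.reproductive_values(A)
    fit_tab = fitness_mod.fitness_table(
        dataset.individuals, dataset.states, dataset.parentage, cohort_ids, rv
    )
    covs = covariate_table(dataset, offspring_f, pairs_k)
    data = fit_tab.merge(covs, on="id", how="inner")
    data = data[data["f"].notna() & data["k"].notna()].reset_index(drop=True)

    base = ModelSpec(response="W", family="hurdle", groups=("mother", "nest"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        selection = all_subset_selection(data, base, candidates, exclusive)
    best_terms = selection.best_terms

    halfsib = paired_halfsib_table(
        data.rename(columns={"id": "id"}), ["W"], seed=dataset.config.seed if hasattr(dataset, "config") else 0
    )
    if len(halfsib) >= 2:
        wres = wilcoxon_paired(halfsib["epo_W"], halfsib["wpo_W"])
        wilcox = {"V": wres.V, "p": wres.p, "n_pairs": int(len(halfsib))}
    else:
        wilcox = {"V": None, "p": None, "n_pairs": int(len(halfsib))}

    inbred = data["inbred"] > 0
    mean_w_inbred = float(data.loc[inbred, "W"].mean()) if inbred.any() else float("nan")
    mean_w_non = float(data.loc[~inbred, "W"].mean())
    upairs = pairs_k.dropna(subset=["k"])
    report = {
        "n_offspring": int(len(data)),
        "n_social_pairs": int(len(upairs)),
        "epp_rate": float(data["epp"].mean()),
        "pct_close_kin_pairs": float(100 * upairs["close_kin"].mean()),
        "pct_first_order_pairs": float(100 * (upairs["k"] > 0.22).mean()),
        "pct_inbred_offspring": float(100 * inbred.mean()),
        "pct_first_order_offspring": float(100 * (data["f"] > 0.22).mean()),
        "mean_f_epo": float(data.loc[data["epp"] > 0, "f"].mean()),
        "mean_f_wpo": float(data.loc[data["epp"] == 0, "f"].mean()),
        "mean_W_inbred": mean_w_inbred,
        "mean_W_noninbred": mean_w_non,
        "inbred_fitness_ratio": mean_w_inbred / mean_w_non if mean_w_non > 0 else float("nan"),
        "lambda": float(rv.lam),
        "rv": {f"{st}_{sx}": float(v) for (st, sx), v in rv.v.items()},
        "best_model_terms": list(best_terms),
        "inbred_term_in_best": "inbred" in best_terms,
        "epp_term_in_best": any("epp" in t for t in best_terms),
        "inbred_akaike_weight": selection.weight_of("inbred"),
        "wilcoxon_epo_wpo": wilcox,
        "runtime_s": round(time.time() - t0, 2),
    }
    if hasattr(dataset, "config"):
        report["seed"] = dataset.config.seed

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        offspring_f.to_csv(out_dir / "offspring_f.csv", index=False)
        pairs_k.to_csv(out_dir / "pairs_k.csv", index=False)
        dyads.to_csv(out_dir / "dyads.csv", index=False)
        rv.to_frame().to_csv(out_dir / "rv.csv", index=False)
        np.savetxt(out_dir / "projection_matrix.csv", A, delimiter=",")
        fit_tab.to_csv(out_dir / "fitness.csv", index=False)
        covs.to_csv(out_dir / "covariates.csv", index=False)
        tab = selection.table.copy()
        tab["terms"] = tab["terms"].map(lambda ts: " + ".join(ts) if ts else "(null)")
        tab.to_csv(out_dir / "selection_fitness.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
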