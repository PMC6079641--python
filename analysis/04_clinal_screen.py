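#!/usr/bin/env python
"""Screen tree-ring traits for clinal variation along provenance climate.

Mantel tests relate growth-similarity among populations to geographic and
climatic distance; each population trait (type A/B and screened CS traits) is
then regressed on MAT_p (linear vs quadratic, AIC-selected, block-size
covariate dropped when non-significant). Traits with p < 0.01 pass to the
association stage. Writes results/clinal/clinal_fits.tsv and mantel.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ringpheno.clinal import (
    ProvenanceRecord,
    chronology_distance,
    fit_clinal_model,
    mantel_test,
    select_traits_for_gpa,
)
from ringpheno.pipeline import build_chronologies
from ringpheno.ringchron import read_long_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--traits", type=Path, default=Path("results/traits"))
    ap.add_argument("--out", type=Path, default=Path("results/clinal"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    prov_df = pd.read_csv(args.dataset / "provenances.csv")
    provenances = [ProvenanceRecord(**r) for r in prov_df.to_dict("records")]
    mats = prov_df.set_index("population_id")["mat_p"]

    rings = read_long_csv(args.dataset / "rings.csv")
    _, pop_chron, _ = build_chronologies(rings, 1993, 2014)

    dists = chronology_distance(pop_chron, provenances)
    mantel_rows = []
    for label, other in (("geo", "geographic distance"), ("dmat", "|dMAT_p|")):
        res = mantel_test(dists["growth"].to_numpy(), dists[label].to_numpy(),
                          n_perm=999, seed=args.seed, label=other)
        mantel_rows.append({"pair": f"growth vs {other}", "r": res.r, "p": res.p})
        print(f"Mantel growth-dissimilarity vs {other}: r = {res.r:+.2f}, p = {res.p:.3f}")

    pop_traits = pd.read_csv(args.traits / "population_traits.csv").set_index(
        "population_id"
    )
    cs = pd.read_csv(args.traits / "cs_population.tsv", sep="\t")
    sig_counts = cs.groupby(["variable", "month_label"])["significant"].sum()
    for (var, lab), cnt in sig_counts.items():
        if cnt >= 5:
            wide = cs[(cs.variable == var) & (cs.month_label == lab)].set_index(
                "unit_id"
            )["r"]
            pop_traits[f"CS_BAI-{var}.{lab}"] = wide

    pids = pop_traits.index.to_list()
    fits = []
    for name in pop_traits.columns:
        fits.append(
            fit_clinal_model(
                pop_traits[name].to_numpy(), mats.loc[pids].to_numpy(),
                trait_name=name, allow_quadratic=not name.startswith("CS_"),
            )
        )
    selected = select_traits_for_gpa(fits)
    out_rows = [
        {"trait": f.trait, "model": f.model, "aic_lin": f.aic_linear,
         "aic_quad": f.aic_quadratic, "adj_r2": f.adj_r2, "p": f.p_value,
         "slope_sign": f.slope_sign, "selected": f.trait in selected}
        for f in fits
    ]
    df = pd.DataFrame(out_rows)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print(f"selected for association (p < 0.01): {', '.join(selected) or 'none'}")

    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "clinal_fits.tsv", sep="\t", index=False)
    pd.DataFrame(mantel_rows).to_csv(args.out / "mantel.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
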