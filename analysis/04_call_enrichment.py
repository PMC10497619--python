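"""Call enriched and depleted elements per sorted population.

Normalizes counts to percent abundance, computes fold change of each
element in each gate against the pDNA pool and a Welch t-test across
replicates, and calls hits at FC > 1.5 / FC < 0.67 with p < 0.05. Reports
pDNA coverage, replicate correlations, hit composition by library
category, and phenotype-recovery metrics against the simulation ground
truth; writes enrichment, volcano and heatmap tables.
"""

import argparse
from pathlib import Path

import pandas as pd

from barrierscreen import enrichment as en
from barrierscreen import library_design as ld


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--library-dir", type=Path, default=Path("results/library"))
    ap.add_argument("--screen-dir", type=Path, default=Path("results/screen"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/enrichment"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(args.screen_dir / "counts.tsv", sep="\t", index_col=0)
    sheet = pd.read_csv(args.screen_dir / "sample_sheet.tsv", sep="\t")
    truth = pd.read_csv(args.screen_dir / "ground_truth.tsv", sep="\t", index_col=0)
    manifest = ld.read_manifest(args.library_dir / "manifest.tsv").set_index("id")

    abundance = en.relative_abundance(counts)
    abundance.to_csv(args.out_dir / "abundance.tsv", sep="\t")

    pdna_cols = sheet.loc[sheet["role"] == "pdna", "sample"]
    cov, curve = en.coverage_and_cumulative(abundance[pdna_cols].mean(axis=1).to_numpy())
    curve.to_csv(args.out_dir / "pdna_cumulative.tsv", sep="\t", index=False)
    print(f"pDNA library coverage: {cov:.1f}% of designed elements")

    corrs = []
    for (pop, day), grp in sheet[sheet["role"] == "sorted"].groupby(["population", "day"]):
        cols = list(grp["sample"])
        if len(cols) == 2:
            r = en.replicate_correlation(abundance[cols[0]], abundance[cols[1]])
            corrs.append({"population": pop, "day": day, "pearson_r": r})
    corr_df = pd.DataFrame(corrs)
    corr_df.to_csv(args.out_dir / "replicate_correlations.tsv", sep="\t", index=False)
    print(f"mean replicate correlation (log10 abundance): "
          f"{en.mean_correlation(corr_df['pearson_r']):.2f}")

    results = en.compute_enrichment(abundance, sheet)
    results = results.merge(
        manifest["category_label"], left_on="element_id", right_index=True
    )
    results.to_csv(args.out_dir / "enrichment.tsv", sep="\t", index=False)
    en.volcano_table(results).to_csv(args.out_dir / "volcano.tsv", sep="\t", index=False)
    en.heatmap_matrix(abundance, sheet).to_csv(args.out_dir / "heatmap.tsv", sep="\t")

    for pop in ("Negative", "Low", "Medium", "High"):
        sub = results[results["population"] == pop]
        hits = sub.loc[sub["call"] == "enriched", "element_id"].tolist()
        print(f"{pop}: {len(hits)} enriched elements")
        if hits:
            comp = en.hit_composition(hits, manifest["category_label"].to_dict())
            comp.to_csv(args.out_dir / f"hit_composition_{pop}.tsv", sep="\t")
            top = comp["percent"].idxmax()
            print(f"  dominant category: {top} ({comp.loc[top, 'percent']:.0f}%)")

    high = results[results["population"] == "High"].set_index("element_id")
    neg = results[results["population"] == "Negative"].set_index("element_id")
    strong = truth.index[truth["barrier_strength"] >= 0.9]
    null = truth.index[truth["barrier_strength"] == 0.0]
    print(f"strong barriers recovered in High gate: "
          f"{100 * (high.loc[strong, 'call'] == 'enriched').mean():.0f}%")
    print(f"null controls recovered in Negative gate: "
          f"{100 * (neg.loc[null, 'call'] == 'enriched').mean():.0f}%")
    print(f"null false positives in High gate: "
          f"{100 * (high.loc[null, 'call'] == 'enriched').mean():.0f}%")


if __name__ == "__main__":
    main()
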