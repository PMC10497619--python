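"""Compare sequence features across enrichment-defined element sets.

Computes GC content per library category, counts the USF E-box (CANNTG)
and VEZF1 G-tract (GGGG) motifs in elements enriched in each sorted
population (restricting the crowded Negative hit list to its top 50 by
fold change), runs pairwise Welch t-tests with box statistics, and builds
per-family position frequency matrices with information-content profiles.
"""

import argparse
from pathlib import Path

import pandas as pd

from barrierscreen import library_design as ld
from barrierscreen import sequence_features as sf


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--library-dir", type=Path, default=Path("results/library"))
    ap.add_argument("--enrichment-dir", type=Path, default=Path("results/enrichment"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/features"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    library = ld.read_library_fasta(args.library_dir / "library_cores.fasta", oligo=False)
    manifest = ld.read_manifest(args.library_dir / "manifest.tsv").set_index("id")
    seqs = {el.id: el.core_sequence for el in library}
    results = pd.read_csv(args.enrichment_dir / "enrichment.tsv", sep="\t")

    # GC content across library categories
    gc_by_cat = {
        cat: [100 * sf.gc_content(seqs[i]) for i in grp.index]
        for cat, grp in manifest.groupby("category_label")
    }
    gc_p, gc_stats = sf.compare_feature_across_sets(gc_by_cat)
    gc_stats.to_csv(args.out_dir / "gc_by_category.tsv", sep="\t")
    gc_p.to_csv(args.out_dir / "gc_pairwise_p.tsv", sep="\t", index=False)
    print("GC content (%) per category:")
    print(gc_stats[["n", "median", "mean"]].round(1).to_string())

    # motif counts across enrichment-defined sets
    def hit_ids(pop: str) -> list[str]:
        sub = results[(results["population"] == pop) & (results["call"] == "enriched")]
        if pop == "Negative":
            return sf.top_enriched_subset(
                results[results["call"] == "enriched"], pop, 50
            )
        return sub["element_id"].tolist()

    for motif, fname in ((sf.USF_MOTIF, "usf"), (sf.VEZF1_MOTIF, "vezf1")):
        sets = {}
        for pop in ("Negative", "Low", "Medium", "High"):
            ids = hit_ids(pop)
            if len(ids) >= 2:
                sets[pop] = [float(sf.count_motif(seqs[i], motif)) for i in ids]
        pvals, stats = sf.compare_feature_across_sets(sets)
        stats.to_csv(args.out_dir / f"{fname}_motif_stats.tsv", sep="\t")
        pvals.to_csv(args.out_dir / f"{fname}_pairwise_p.tsv", sep="\t", index=False)
        print(f"{motif.name} motif ({motif.pattern}) per enriched set — "
              f"medians: " + ", ".join(f"{k}={v:.1f}" for k, v in stats["median"].items()))

    # information-content profiles per element family
    for family, prefix in (("CTCF-High", "ctcf_high"), ("MIR-random", "mir")):
        fam_ids = manifest.index[manifest["category_label"] == family]
        pfm = sf.build_pfm([seqs[i] for i in fam_ids])
        ic = sf.information_content(pfm)
        pd.DataFrame({"position": range(1, pfm.length + 1), "bits": ic}).to_csv(
            args.out_dir / f"{prefix}_information_content.tsv", sep="\t", index=False
        )
        print(f"{family}: max per-position information {ic.max():.2f} bits "
              f"(position {ic.argmax() + 1})")


if __name__ == "__main__":
    main()
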