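"""Simulate the sort-seq screen over the designed library.

Assigns each element a latent barrier strength (50 strong barriers, 50
inert null controls, partially protective background), simulates day-15
cell populations, sorts them into the four EGFP gates with two biological
replicates, and sequences each gate plus the pDNA pool (two technical
replicates) to 100,000 reads. Writes the count matrix, sample sheet and
ground-truth manifest, plus two demonstration FASTQ files for the mapping
step: one noiseless sample (for exact count recovery) and one with the
full error model.
"""

import argparse
from pathlib import Path

from barrierscreen import library_design as ld
from barrierscreen import synthetic_screen as ss


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=307)
    ap.add_argument("--library-dir", type=Path, default=Path("results/library"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/screen"))
    ap.add_argument("--reads-per-sample", type=int, default=100_000)
    ap.add_argument("--fastq-reads", type=int, default=20_000,
                    help="reads per demonstration FASTQ")
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    library = ld.read_library_fasta(args.library_dir / "oligo_pool.fasta", oligo=True)
    ids = [el.id for el in library]
    manifest = ld.read_manifest(args.library_dir / "manifest.tsv").set_index("id")
    cat = manifest["category_label"]
    # nulls = the 50 random-sequence controls; strong barriers = the 30
    # LAD-bound MIRs plus the 20 top-ranked high-affinity CTCF elements
    null_ids = list(cat.index[cat == "RANDOM"])
    strong_ids = list(cat.index[cat == "MIR-LAD_bound"]) + list(
        cat.index[cat == "CTCF-High"][:20]
    )
    phenos = ss.generate_phenotypes(
        ids, seed=args.seed, strong_ids=strong_ids, null_ids=null_ids
    )

    res = ss.simulate_screen(
        library, phenos, days=(15,), replicates=2, cells_per_element=1000,
        reads_per_sample=args.reads_per_sample, seed=args.seed,
    )
    res.counts.to_csv(args.out_dir / "counts.tsv", sep="\t")
    res.sample_sheet.to_csv(args.out_dir / "sample_sheet.tsv", sep="\t", index=False)
    ss.write_ground_truth(res.ground_truth, args.out_dir / "ground_truth.tsv")

    b = res.ground_truth["barrier_strength"]
    print(f"simulated {res.counts.shape[1]} samples over {len(ids)} elements "
          f"({(b >= 0.9).sum()} strong, {(b == 0).sum()} null)")
    print(f"counts written to {args.out_dir/'counts.tsv'}")

    # demonstration FASTQs for the mapping step (one gate, day 15, rep 1)
    noiseless = ss.SequencingConfig(
        read_length=250, substitution_rate=0, insertion_rate=0, deletion_rate=0,
        pcr_noise_sigma=0,
    )
    noisy = ss.SequencingConfig(read_length=250)
    for tag, cfg in (("noiseless", noiseless), ("noisy", noisy)):
        demo = ss.simulate_screen(
            library, phenos, days=(15,), replicates=1, cells_per_element=500,
            reads_per_sample=args.fastq_reads, cfg=cfg, dropout_fraction=0.0,
            seed=args.seed + 1, emit_fastq=True,
        )
        sample = "High_d15_r1"
        ss.write_fastq(demo.reads[sample], args.out_dir / f"{tag}_{sample}.fastq")
        demo.counts[[sample]].to_csv(
            args.out_dir / f"{tag}_{sample}_true_counts.tsv", sep="\t"
        )
        print(f"wrote {tag} FASTQ ({args.fastq_reads} reads) for sample {sample}")


if __name__ == "__main__":
    main()
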