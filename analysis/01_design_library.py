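"""Assemble the 1000-element barrier screening library.

Generates the upstream candidate resources (scored CTCF-binding sites, MIR
elements with genomic coordinates, LAD intervals), applies the composition
rules (top-450 / bottom-50 CTCF ranking, <5 kb LAD-boundary proximity for
the MIR_LAD-bound quota, 50 random controls, Esp3I exclusion, 250 bp
centered cores, 25+25 bp cloning flanks) and writes the library FASTA,
oligo pool and manifest. Also prints the coverage-planning arithmetic used
to size transformations and transfections.
"""

import argparse
from collections import Counter
from pathlib import Path

from barrierscreen import library_design as ld
from barrierscreen import synthetic_screen as ss


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out-dir", type=Path, default=Path("results/library"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    res = ss.generate_candidate_resources(seed=args.seed)
    ld.write_candidate_table(res["ctcf"] + res["mir"], args.out_dir / "candidates.tsv")
    ld.write_bed(res["lads"], args.out_dir / "lads.bed")

    near, far = ld.lad_proximity_filter(res["mir"], res["lads"], 5000)
    print(f"MIR candidates within 5 kb of a LAD boundary: {len(near)} of {len(res['mir'])}")

    library = ld.assemble_library(res["ctcf"], res["mir"], res["lads"], seed=args.seed)
    ld.write_library_fasta(library, args.out_dir / "library_cores.fasta", oligo=False)
    ld.write_library_fasta(library, args.out_dir / "oligo_pool.fasta", oligo=True)
    ld.write_manifest(library, args.out_dir / "manifest.tsv")

    counts = Counter(el.category_label for el in library)
    print(f"assembled library: {len(library)} elements "
          f"({', '.join(f'{k}={v}' for k, v in sorted(counts.items()))})")
    print(f"core length 250 bp, oligo length {len(library[0].oligo_sequence)} bp")

    clones = ld.expected_clones(24, 600_000, 0.004)
    print(f"expected clones from 24 transfections at 0.4% integration: {clones} "
          f"({ld.fold_coverage(clones, len(library)):.1f}-fold library coverage)")
    for cfu in (4.72e5, 8.42e5):
        print(f"transformation at {cfu:.3g} CFU: "
              f"{ld.fold_coverage(cfu, len(library)):.0f}-fold coverage")


if __name__ == "__main__":
    main()
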