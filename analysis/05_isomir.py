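#!/usr/bin/env python
"""Step 5 - isomiR classification and summary.

Aligns every conserved-miRNA tag to its canonical mature sequence,
classifies the variant (5'/3'/internal, templated vs non-templated
additions), and writes per-tag records plus read-weighted class fractions
under results/isomir/.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from smallrna import isomir


def read_fasta(path):
    out, name = {}, None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name:
            out[name] += line.strip()
    return out


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--tags", type=Path, default=Path("results/preprocess/tags.tsv"))
    parser.add_argument(
        "--annotation", type=Path, default=Path("results/annotate/annotation.tsv")
    )
    parser.add_argument("--out", type=Path, default=Path("results/isomir"))
    args = parser.parse_args()

    tag_df = pd.read_csv(args.tags, sep="\t").set_index("tag_id")
    ann = pd.read_csv(args.annotation, sep="\t")
    conserved = ann[ann["category"] == "conserved_mirna"]
    matures = read_fasta(args.sim / "mature_known.fa")

    # strand-local context with flanks, from the locus manifest + genome
    genome = "".join(read_fasta(args.sim / "genome.fa").values())
    contexts = {}
    for line in (args.sim / "loci.gff3").read_text().splitlines():
        if "\tpre_miRNA\t" not in line:
            continue
        f = line.split("\t")
        gid = f[8].split("ID=")[1].split(";")[0]
        lo, hi = int(f[3]) - 1, int(f[4])
        seq = genome[max(0, lo - 30) : hi + 30].upper().replace("T", "U")
        if f[6] == "-":
            comp = str.maketrans("ACGU", "UGCA")
            seq = seq.translate(comp)[::-1]
        contexts[gid] = seq

    records = []
    skipped = 0
    for row in conserved.itertuples():
        gene = row.reference_id
        canonical = matures[gene]
        try:
            aln = isomir.align_to_canonical(tag_df.loc[row.tag_id, "sequence"], canonical)
            rec = isomir.classify_isomir(
                aln, contexts.get(gene), mirna_id=gene, tag_id=row.tag_id,
                count=int(tag_df.loc[row.tag_id, "count"]),
            )
            records.append(rec)
        except ValueError:
            skipped += 1

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id, "tag_id": r.tag_id, "count": r.count,
                "class": r.isomir_class, "subtype5": r.subtype5,
                "subtype3": r.subtype3, "offset5": r.offset5, "offset3": r.offset3,
                "n_substitutions": len(r.substitutions),
            }
            for r in records
        ]
    ).to_csv(args.out / "isomir_records.tsv", sep="\t", index=False)

    summary = isomir.summarize_isomirs(records)
    payload = {
        "n_reads": summary.n_reads,
        "read_fractions": summary.read_fractions,
        "noncanonical_read_fractions": summary.noncanonical_read_fractions,
        "iso3_trim_fraction": summary.iso3_trim_fraction,
    }
    (args.out / "summary.json").write_text(json.dumps(payload, indent=2) + "\n")
    summary.per_mirna_isomirs.to_csv(
        args.out / "per_mirna_isomirs.tsv", sep="\t", index=False
    )

    print(f"classified {len(records)} conserved tags ({skipped} unassignable)")
    for cls, frac in summary.read_fractions.items():
        print(f"  {cls:<10} {100 * frac:6.2f} % of reads")
    print(f"  3' trims account for {100 * summary.iso3_trim_fraction:.2f} % of 3' isomiRs")


if __name__ == "__main__":
    main()
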