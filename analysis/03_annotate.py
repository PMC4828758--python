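#!/usr/bin/env python
"""Step 3 - hierarchical annotation of unique tags.

Matches tags against the known mature-miRNA set and the rRNA/tRNA/snoRNA
references, maps the rest to the toy genome, and writes per-tag annotation
records plus a read-statistics table with percentages under
results/annotate/.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from smallrna import annotate, preprocess, report


def read_fasta(path):
    out = {}
    name = None
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
    parser.add_argument("--out", type=Path, default=Path("results/annotate"))
    args = parser.parse_args()

    tag_df = pd.read_csv(args.tags, sep="\t")
    tags = [
        preprocess.UniqueTag(r.tag_id, r.sequence, int(r.count))
        for r in tag_df.itertuples()
    ]
    genome = "".join(read_fasta(args.sim / "genome.fa").values())
    ref_sets = {
        "mature": read_fasta(args.sim / "mature_known.fa"),
        "rrna": read_fasta(args.sim / "rrna.fa"),
        "trna": read_fasta(args.sim / "trna.fa"),
        "snorna": read_fasta(args.sim / "snorna.fa"),
    }
    result = annotate.classify(tags, genome, ref_sets)

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(r.tag_id, r.category, r.reference_id, r.n_mismatches) for r in result.records],
        columns=["tag_id", "category", "reference_id", "n_mismatches"],
    ).to_csv(args.out / "annotation.tsv", sep="\t", index=False)
    rows = [
        aln
        for alns in result.alignments.values()
        for aln in alns
    ]
    pd.DataFrame(
        [(a.tag_id, a.chrom, a.start, a.end, a.strand, a.n_mismatches) for a in rows],
        columns=["tag_id", "chrom", "start", "end", "strand", "n_mismatches"],
    ).to_csv(args.out / "novel_input_alignments.tsv", sep="\t", index=False)

    high_quality = int(result.counts["total_reads"].sum())
    stats = report.category_stats(
        [
            (row.category, int(row.total_reads), int(row.unique_tags))
            for row in result.counts.itertuples()
        ],
        high_quality_total=high_quality,
    )
    stats.to_csv(args.out / "read_statistics.tsv", sep="\t", index=False)
    print(stats.to_string(index=False))
    print(f"-> {args.out}/annotation.tsv, read_statistics.tsv")


if __name__ == "__main__":
    main()
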