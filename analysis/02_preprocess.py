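#!/usr/bin/env python
"""Step 2 - preprocess the raw library into unique tags.

Quality filter -> 3'-adapter trim -> 18-30 nt length filter -> collapse to
unique tags with counts.  Reads results/sim/reads.fastq, writes the tag
table, collapsed FASTA and stage statistics under results/preprocess/.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from smallrna import preprocess
from smallrna.simdata import DEFAULT_ADAPTER3


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fastq", type=Path, default=Path("results/sim/reads.fastq"))
    parser.add_argument("--adapter", default=DEFAULT_ADAPTER3)
    parser.add_argument("--out", type=Path, default=Path("results/preprocess"))
    args = parser.parse_args()

    res = preprocess.run_fastq(str(args.fastq), args.adapter)
    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(t.tag_id, t.sequence, t.count) for t in res.tags],
        columns=["tag_id", "sequence", "count"],
    ).to_csv(args.out / "tags.tsv", sep="\t", index=False)
    preprocess.write_collapsed_fasta(res.tags, args.out / "tags.fa")
    stats = res.stats
    (args.out / "stats.json").write_text(json.dumps(vars(stats), indent=2) + "\n")

    print(f"raw reads:        {stats.raw_reads:,}")
    print(f"quality-passing:  {stats.post_quality:,}")
    print(f"adapter-trimmed:  {stats.post_adapter:,}")
    print(f"18-30 nt:         {stats.post_length:,}")
    print(f"unique tags:      {stats.unique_tags:,} -> {args.out}/tags.tsv")


if __name__ == "__main__":
    main()
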