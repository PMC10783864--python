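"""Convert externally obtained lysine PTM site tables to segments_tsv.

Converter contract
------------------
Input is a delimited text table with one row per lysine site carrying, in
some column layout, (a) a protein accession, (b) a 1-based lysine position
or a pre-extracted peptide window, and (c) the site's PTM annotations.
Column names are mapped with the ``--col-*`` flags, so both the published
benchmark dialects fit:

* the UniProt-derived multi-label benchmark (6394 sites, window length 27,
  i.e. half width 13) distributed as study supplementary material, and
* the CPLM 4.0-derived training/testing tables (window half width 24).

Annotations may be a single delimited column of type names
(``--col-labels``) or four separate 0/1-ish indicator columns
(``--flag-columns``).  Output is the canonical segments_tsv consumed by
``lysptm``.  ``--expect-records`` makes the conversion fail loudly when
the row count is not the published one (use 6394 for the UniProt-derived
benchmark), which guards against truncated downloads.

Example:
    python scripts/convert_external.py qiu_supplementary.txt qiu.segments.tsv \
        --col-segment peptide --col-labels modification --label-sep ";" \
        --expect-records 6394
"""

from __future__ import annotations

import argparse
import sys

import pandas as pd

from lysptm.segments import PTM_TYPES, Dataset, labels_to_vector, save_segments_tsv
import numpy as np


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    parser.add_argument("input")
    parser.add_argument("output")
    parser.add_argument("--sep", default="\t", help="input field separator")
    parser.add_argument("--col-protein", default="protein_id")
    parser.add_argument("--col-position", default="position")
    parser.add_argument("--col-segment", default="segment",
                        help="column holding the pre-extracted window")
    parser.add_argument("--col-labels", default=None,
                        help="single column of delimited type names")
    parser.add_argument("--label-sep", default=",")
    parser.add_argument("--flag-columns", nargs=4, default=None,
                        metavar=("ACE", "CRO", "MET", "SUC"),
                        help="four 0/1 indicator columns, in canonical type order")
    parser.add_argument("--expect-records", type=int, default=None)
    args = parser.parse_args(argv)

    df = pd.read_csv(args.input, sep=args.sep, keep_default_na=False)
    if args.expect_records is not None and len(df) != args.expect_records:
        parser.error(f"expected {args.expect_records} records, found {len(df)}")
    if args.flag_columns:
        labels = np.array([
            [1 if str(row[c]).strip() not in ("", "0", "x", "X", "-") else -1
             for c in args.flag_columns]
            for _, row in df.iterrows()
        ], dtype=np.int8)
    elif args.col_labels:
        labels = np.array([
            labels_to_vector(str(v).split(args.label_sep))
            for v in df[args.col_labels]
        ])
    else:
        parser.error("provide --col-labels or --flag-columns")
    segments = [str(s).strip().upper() for s in df[args.col_segment]]
    half_width = len(segments[0]) // 2
    protein_ids = (df[args.col_protein].astype(str).tolist()
                   if args.col_protein in df.columns
                   else [f"UNK{i}" for i in range(len(df))])
    positions = (df[args.col_position].to_numpy()
                 if args.col_position in df.columns
                 else np.arange(1, len(df) + 1))
    ds = Dataset(protein_ids, positions, segments, labels, half_width)
    save_segments_tsv(ds, args.output)
    print(f"wrote {len(ds)} records (L={half_width}) to {args.output}",
          file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
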