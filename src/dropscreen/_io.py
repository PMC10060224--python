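"""Shared TSV reading with full-line '#' comments.

Guide ids legitimately contain '#' (sgK#1), so pandas' in-line ``comment=``
handling would truncate data rows; only lines *starting* with '#' are
comments in this package's dialect.
"""

from __future__ import annotations

import io

import pandas as pd


def read_tsv(path, **kwargs) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        text = "".join(
            line for line in fh if not line.lstrip().startswith("#")
        )
    return pd.read_csv(io.StringIO(text), sep="\t", **kwargs)
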