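"""Tab-separated table I/O with provenance header comments.

All tables produced by this package are plain TSV with a column header,
optionally preceded by ``# key: value`` comment lines recording the tool
version, seed and thresholds of the run that produced them.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd

from . import __version__


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, meta: Mapping | None = None) -> None:
    """Write *df* as TSV, prefixed by ``# key: value`` provenance comments."""
    with open(path, "w") as fh:
        fh.write(f"# tucseq_version: {__version__}\n")
        if meta:
            for key, value in meta.items():
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (comment lines are skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_meta(path: str | os.PathLike) -> dict:
    """Return the ``# key: value`` comment header of a TSV as a dict."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    return meta
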