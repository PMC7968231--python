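"""Report-layer arithmetic and bit-stable TSV I/O.

All percentages and densities printed in run summaries go through the two
helpers here, rounded only at the report layer.  Every TSV written by the
toolkit carries a ``# indelkit=<version> config=<hash>`` header so that
runs with different parameters are distinguishable and identical runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from typing import Mapping, Optional

import pandas as pd

from . import __version__


def pct(part: float, whole: float, decimals: int = 2) -> float:
    """Percentage at the printed precision (e.g. 2502/3140 -> 79.68)."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round(100.0 * part / whole, decimals)


def density_per_mb(count: float, length_mb: float, decimals: Optional[int] = 0) -> float:
    """Loci per megabase (e.g. 389487 over 300 Mb -> 1298)."""
    if length_mb <= 0:
        raise ValueError("non-positive length")
    d = count / length_mb
    return round(d, decimals) if decimals is not None else d


def config_hash(params: Mapping) -> str:
    """Stable short hash of a resolved parameter mapping."""
    blob = json.dumps({str(k): params[k] for k in sorted(params, key=str)},
                      sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, params: Optional[Mapping] = None,
              float_format: str = "%.6f") -> None:
    """Atomic TSV write with a config-hash header comment."""
    path = str(path)
    h = config_hash(params or {})
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(path) or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(f"# indelkit={__version__} config={h}\n")
            df.to_csv(fh, sep="\t", index=False, float_format=float_format)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
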