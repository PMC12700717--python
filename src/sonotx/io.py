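"""File formats: grayscale PNG images/masks, TSV/CSV tables, GMT gene sets.

All tabular output is UTF-8 with a header row and floats at 10 significant
digits, so reruns with a fixed seed are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

FLOAT_FORMAT = "%.10g"


def write_image_png(path, image: np.ndarray) -> None:
    """8-bit grayscale PNG; float input is clipped to [0, 255]."""
    arr = np.clip(np.asarray(image, dtype=float), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def write_mask_png(path, mask: np.ndarray) -> None:
    arr = np.where(np.asarray(mask).astype(bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=float)


def read_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    df.to_csv(path, sep=sep, index=index, float_format=FLOAT_FORMAT)


def read_table(path, index_col=0) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    return pd.read_csv(path, sep=sep, index_col=index_col)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set collection: name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_tics_csv(tics, path) -> None:
    rows = []
    for sid in sorted(tics):
        tic = tics[sid]
        for t, i in zip(tic.t, tic.intensity):
            rows.append({"subject_id": sid, "t": t, "intensity": i})
    write_table(pd.DataFrame(rows), path, index=False)
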