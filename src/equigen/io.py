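"""Text I/O: a PLINK-raw-style additive dosage dialect and truth sidecars.

The dosage table is tab-separated with a header row
``FID IID PHENOTYPE <snp ids...>`` and one row per individual carrying the
family/individual identifiers, the case/control phenotype (1/0) and the
additive dosages (0/1/2, ``NA`` for missing). The sidecar truth file
records, per SNP, the EUR and DDP effect sizes; a header block of ``#key
value`` lines carries the scalar truth (rho, h2, thresholds, distances).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth_data import EffectModel, MultiAncestryDataset


def write_dosage_table(data: MultiAncestryDataset, path: str | Path) -> None:
    path = Path(path)
    snp_ids = data.snp_ids or [f"snp{j}" for j in range(data.X.shape[1])]
    df = pd.DataFrame(data.X, columns=snp_ids)
    df.insert(0, "PHENOTYPE", data.y)
    df.insert(0, "IID", [f"i{k}" for k in range(len(data.y))])
    df.insert(0, "FID", data.ancestry)
    df.insert(3, "SPLIT", data.split)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_table(path: str | Path):
    """Read a dosage table; returns (X, y, ancestry, split, snp_ids).

    ``SPLIT`` is optional; foreign PLINK-raw-like exports without it get
    an all-"train" assignment.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta = [c for c in ("FID", "IID", "PHENOTYPE", "SPLIT") if c in df.columns]
    snp_ids = [c for c in df.columns if c not in meta]
    X = df[snp_ids].to_numpy(dtype=float)
    y = df["PHENOTYPE"].to_numpy(dtype=np.int8)
    ancestry = df["FID"].to_numpy(dtype=str)
    split = (df["SPLIT"].to_numpy(dtype=str) if "SPLIT" in df.columns
             else np.full(len(y), "train"))
    return X, y, ancestry, split, snp_ids


def write_truth_sidecar(data: MultiAncestryDataset, path: str | Path) -> None:
    if data.effect_model is None:
        raise ValueError("dataset carries no effect model (not synthetic?)")
    em: EffectModel = data.effect_model
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#rho\t{float(em.rho)!r}\n")
        fh.write(f"#h2\t{float(em.h2)!r}\n")
        for pop, thr in data.thresholds.items():
            fh.write(f"#thr_{pop}\t{float(thr)!r}\n")
        fh.write("snp_id\tW\tW_prime\n")
        snp_ids = data.snp_ids or [f"snp{j}" for j in range(len(em.W))]
        for sid, w, wp in zip(snp_ids, em.W, em.W_prime):
            fh.write(f"{sid}\t{float(w)!r}\t{float(wp)!r}\n")


def read_truth_sidecar(path: str | Path):
    """Returns (scalars dict, per-SNP DataFrame)."""
    scalars: dict[str, float] = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, val = line[1:].split("\t")
            scalars[key] = float(val)
        else:
            body_start = i
            break
    import io as _io

    table = pd.read_csv(
        _io.StringIO("\n".join(lines[body_start:])), sep="\t",
        float_precision="round_trip",
    )
    return scalars, table
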