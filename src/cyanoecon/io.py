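"""Readers and writers for the tabular formats the pipeline consumes.

All tables are TSV with a header; floats are serialized at 6 significant
digits; nested reports are JSON.  The proteomics reader understands the
MaxQuant proteinGroups conventions (``LFQ intensity <sample>`` /
``iBAQ <sample>`` columns, ``Peptides``, ``Potential contaminant`` and
``Reverse`` flags, zero intensities meaning missing).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fitting import GrowthObservation
from .proteome import IntensityMatrix

REQUIRED_COLUMNS = ("Majority protein IDs", "Peptides",
                    "Potential contaminant", "Reverse")
LFQ_PREFIX = "LFQ intensity "
IBAQ_PREFIX = "iBAQ "


def load_protein_groups(path, groups: Mapping[str, str] | None = None
                        ) -> IntensityMatrix:
    """Read a MaxQuant-style proteinGroups TSV into an IntensityMatrix.

    ``groups`` maps sample name -> condition label; if omitted, a sidecar
    ``<path>.groups.json`` is read.  Zero intensities become NaN
    (missing).  Flag columns use MaxQuant's "+" convention.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    ids = table["Majority protein IDs"].str.split(";").str[0]
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicated protein ids: {dups[:5]}")
    lfq_cols = [c for c in table.columns if c.startswith(LFQ_PREFIX)]
    ibaq_cols = [c for c in table.columns
                 if c.startswith(IBAQ_PREFIX) and c != "iBAQ"]
    if not lfq_cols or not ibaq_cols:
        raise ValueError("no 'LFQ intensity <sample>' / 'iBAQ <sample>' "
                         "columns found")
    samples = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    if groups is None:
        sidecar = path.with_suffix(path.suffix + ".groups.json")
        if not sidecar.exists():
            raise ValueError("no group mapping supplied and no sidecar "
                             f"{sidecar.name} found")
        groups = json.loads(sidecar.read_text())

    def numeric(cols, names):
        block = table[cols].apply(pd.to_numeric, errors="coerce")
        block.columns = names
        block.index = ids
        return block.where(block > 0)  # zero intensity = missing

    lfq = numeric(lfq_cols, samples)
    ibaq = numeric([IBAQ_PREFIX + s for s in samples], samples)
    flags = table.set_index(ids)
    return IntensityMatrix(
        lfq=lfq, ibaq=ibaq,
        peptide_counts=pd.to_numeric(flags["Peptides"]).astype(int),
        contaminant=flags["Potential contaminant"].fillna("") == "+",
        reverse=flags["Reverse"].fillna("") == "+",
        groups=dict(groups))


def write_protein_groups(matrix: IntensityMatrix, path,
                         write_sidecar: bool = True) -> None:
    """Write an IntensityMatrix in the MaxQuant proteinGroups dialect."""
    path = Path(path)
    out = pd.DataFrame({"Majority protein IDs": matrix.protein_ids})
    out["Peptides"] = matrix.peptide_counts.to_numpy()
    out["Potential contaminant"] = np.where(matrix.contaminant, "+", "")
    out["Reverse"] = np.where(matrix.reverse, "+", "")
    for s in matrix.samples:
        out[LFQ_PREFIX + s] = matrix.lfq[s].fillna(0.0).to_numpy()
    for s in matrix.samples:
        out[IBAQ_PREFIX + s] = matrix.ibaq[s].fillna(0.0).to_numpy()
    write_table(out, path)
    if write_sidecar:
        sidecar = path.with_suffix(path.suffix + ".groups.json")
        sidecar.write_text(json.dumps(dict(matrix.groups), indent=1))


def load_observations(path) -> list[GrowthObservation]:
    """Read light--growth observations (columns light, mu, sd)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"light", "mu", "sd"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return [GrowthObservation(I=float(r.light), x=float(r.mu),
                              e=float(r.sd)) for r in df.itertuples()]


def write_observations(obs, path) -> None:
    write_table(pd.DataFrame(
        {"light": [o.I for o in obs], "mu": [o.x for o in obs],
         "sd": [o.e for o in obs]}), path)


def load_annotations(path) -> dict[str, set[str]]:
    """protein -> GO term set from a two-column TSV (protein, go_term)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r[0]), set()).add(str(r[1]))
    return out


def load_slim_map(path) -> dict[str, set[str]]:
    """GO term -> GO-slim category set from a two-column TSV."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r[0]), set()).add(str(r[1]))
    return out


def write_table(df: pd.DataFrame, path, float_digits: int = 6) -> None:
    """TSV writer: header, no index, floats at 6 significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False,
              float_format=f"%.{float_digits}g")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_jsonable) + "\n")


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.ndarray,)):
        return value.tolist()
    if isinstance(value, (set, frozenset)):
        return sorted(value)
    raise TypeError(f"not JSON serializable: {type(value)}")
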