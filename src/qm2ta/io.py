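"""Tab-separated table I/O with provenance comment headers.

All pipeline tables are TSV with a header row; lines starting with ``#``
carry provenance (config hash, model hash, seed) and are skipped on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import FormatError


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression matrix TSV: gene_id column + one FPKM column per condition."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns or df.shape[1] < 2:
        raise FormatError(f"{path}: expected gene_id plus condition columns")
    return df.set_index("gene_id")


def read_differential(path: str | Path, default_kind: str = "gene") -> pd.DataFrame:
    """Differential table TSV: measure_id, [kind], fc, p_adj."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"measure_id", "fc", "p_adj"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if "kind" not in df.columns:
        df["kind"] = default_kind
    if (df["fc"] <= 0).any():
        raise FormatError(f"{path}: fold changes must be > 0")
    if ((df["p_adj"] <= 0) | (df["p_adj"] > 1)).any():
        raise FormatError(f"{path}: adjusted p-values must lie in (0,1]")
    if df.duplicated(["measure_id", "kind"]).any():
        raise FormatError(f"{path}: duplicate measure ids within a kind")
    return df[["measure_id", "kind", "fc", "p_adj"]]


def read_pathways(path: str | Path) -> dict[str, str]:
    """Reaction-to-pathway TSV: reaction_id, pathway."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"reaction_id", "pathway"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns reaction_id, pathway")
    return dict(zip(df["reaction_id"], df["pathway"]))


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    header_lines: Iterable[str] = (),
    index: bool = True,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def config_hash(obj: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def model_hash(model) -> str:
    """Short hash over reaction ids, bounds, stoichiometry and GPRs."""
    parts = []
    for rxn in sorted(model.reactions, key=lambda r: r.id):
        stoich = sorted((m.id, c) for m, c in rxn.metabolites.items())
        parts.append(
            (rxn.id, rxn.lower_bound, rxn.upper_bound, rxn.gene_reaction_rule, stoich)
        )
    return hashlib.sha256(json.dumps(parts, default=str).encode()).hexdigest()[:12]
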