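"""TSV/Newick ingest and emit.

Tables are UTF-8 TSV with one header row; columns named after the domain
type fields; missing values are empty strings or "NA".  Output tables are
sorted by species_id so re-runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, Optional

import pandas as pd

from .phylo import Phylogeny, parse_newick, write_newick

__all__ = [
    "read_table",
    "write_table",
    "read_tree",
    "write_tree",
    "write_manifest",
]

_NA = ["", "NA", "na", "NaN"]


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=True)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    if "species_id" in df.columns:
        df = df.sort_values(
            ["species_id"]
            + [c for c in ("population_label",) if c in df.columns]
        ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tree(path: str | Path) -> Phylogeny:
    return parse_newick(Path(path).read_text())


def write_tree(phy: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(write_newick(phy) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    inputs: Iterable[str | Path] = (),
    config: Optional[Dict] = None,
) -> Path:
    """Run manifest: input hashes, echoed config, package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "necomp_version": __version__,
        "inputs": {
            str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()
        },
        "config": config or {},
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
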