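"""Packaged default map snapshots.

The snapshots shipped with the package are **synthetic**, fixture-scale maps
(see :mod:`genesymcheck.fixtures`) covering the classic trouble cases; they
demonstrate the pipeline and keep the repository download-free.  They are not
HGNC/MGI dumps: for real analyses build a current map with
``genesymcheck build-map`` or ``genesymcheck fetch-map``.
"""

from __future__ import annotations

import io
from importlib.resources import files

from .map_io import load_map
from .model import GeneSymbolMap, Species

__all__ = ["load_default_map"]


def load_default_map(species: Species | str) -> GeneSymbolMap:
    """Load the packaged synthetic demonstration snapshot for a species."""
    species = Species.coerce(species)
    resource = files("genesymcheck") / "data" / f"synthetic_snapshot_{species.value}.tsv"
    return load_map(io.StringIO(resource.read_text(encoding="utf-8")))
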