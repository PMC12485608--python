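"""Gene vocabulary with special tokens.

Integer ids 0..2 are reserved: PAD for padding slots, MASK for masked
expression values, CELL for the global cell node. Gene symbols occupy ids
starting at N_SPECIAL in a fixed, file-defined order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PAD_ID = 0
MASK_ID = 1
GLOBAL_ID = 2
N_SPECIAL = 3
SPECIAL_SYMBOLS = {"<pad>": PAD_ID, "<mask>": MASK_ID, "<cell>": GLOBAL_ID}


class Vocabulary:
    """Bidirectional gene symbol <-> integer id map (plus special tokens)."""

    def __init__(self, symbols):
        symbols = list(symbols)
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate gene symbols in vocabulary")
        overlap = set(symbols) & set(SPECIAL_SYMBOLS)
        if overlap:
            raise ValueError(f"gene symbols collide with special tokens: {overlap}")
        self._symbols = symbols
        self._id = {s: N_SPECIAL + i for i, s in enumerate(symbols)}

    # -- sizes ------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self._symbols)

    def __len__(self) -> int:
        """Total table size including special tokens."""
        return N_SPECIAL + len(self._symbols)

    # -- lookups ----------------------------------------------------------
    def __contains__(self, symbol: str) -> bool:
        return symbol in self._id

    def id_of(self, symbol: str) -> int:
        return self._id[symbol]

    def ids_of(self, symbols) -> np.ndarray:
        return np.array([self._id[s] for s in symbols], dtype=np.int64)

    def symbol_of(self, gene_id: int) -> str:
        return self._symbols[gene_id - N_SPECIAL]

    @property
    def symbols(self) -> list:
        return list(self._symbols)

    @property
    def gene_ids(self) -> np.ndarray:
        """All gene ids (special tokens excluded)."""
        return np.arange(N_SPECIAL, N_SPECIAL + len(self._symbols), dtype=np.int64)

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path):
        pd.DataFrame({"symbol": self._symbols,
                      "id": [self._id[s] for s in self._symbols]}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Vocabulary":
        df = pd.read_csv(path, sep="\t")
        if df["symbol"].duplicated().any():
            raise ValueError(f"duplicate gene symbols in {path}")
        df = df.sort_values("id")
        expected = np.arange(N_SPECIAL, N_SPECIAL + len(df))
        if not np.array_equal(df["id"].to_numpy(), expected):
            raise ValueError("vocabulary ids must be contiguous from "
                             f"{N_SPECIAL} (special tokens are implicit)")
        return cls(df["symbol"].tolist())
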