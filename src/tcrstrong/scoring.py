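"""Expression-unit transforms and geometric-mean gene-signature scores.

FPKM values are converted to TPM by column normalization — each gene's FPKM
divided by the sample's total FPKM, times 1e6 — and then offset by 0.01 so
zeros never enter a logarithm.  Raw counts are converted to CPM the same way.
Because the offset is applied AFTER the ratio step, signature scores computed
from TPM are exactly invariant to any per-sample rescaling of the input FPKM;
adding the offset before normalizing would break that invariance.

A signature score for a sample is the geometric mean of the signature genes'
TPM (or CPM) values, exp(mean(ln x)).  Two signatures are built in:

* ``TCR_STRONG`` — TNFRSF4, ICOS, IRF8, TNIP3, STAT4: genes upregulated
  within 4 h in T cells receiving a strong TCR signal or re-activated under
  anti-PD1 blockade; the score tracks TCR signal strength.
* ``T_ACTIVATION`` — NR4A1, CD69, IL2RA (alias CD25), TNFRSF9: a canonical
  T-cell activation comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "TCR_STRONG",
    "T_ACTIVATION",
    "fpkm_to_tpm",
    "counts_to_cpm",
    "signature_score",
]

UNITS = ("counts", "FPKM", "CPM", "TPM")


@dataclass
class ExpressionMatrix:
    """Gene x sample nonnegative expression values tagged with a unit."""

    data: pd.DataFrame  # index = gene symbols, columns = sample ids
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if self.data.index.duplicated().any():
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols: {dups}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_tsv(cls, path, unit: str) -> "ExpressionMatrix":
        """Read a TSV whose first column is headed ``gene``."""
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "gene":
            raise ValueError("first column of an expression TSV must be 'gene'")
        df = df.set_index("gene")
        return cls(df.astype(float), unit)

    def to_tsv(self, path) -> None:
        self.data.rename_axis("gene").to_csv(path, sep="\t")


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set scored by its geometric mean, with symbol aliases."""

    name: str
    genes: tuple[str, ...]
    alias_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = tuple(dict.fromkeys(self.alias_map.get(g, g) for g in self.genes))
        if len(canon) == 0:
            raise ValueError("signature must contain at least one gene")
        object.__setattr__(self, "genes", canon)

    def resolve(self, available: pd.Index) -> tuple[list[str], list[str]]:
        """Split signature genes into (present, missing) for a matrix index."""
        # the matrix itself may carry alias symbols (e.g. CD25 for IL2RA)
        index_alias = {a: c for a, c in self.alias_map.items() if a in available}
        present, missing = [], []
        for g in self.genes:
            if g in available:
                present.append(g)
            else:
                alias = next((a for a, c in index_alias.items() if c == g), None)
                (present if alias else missing).append(alias or g)
        return present, missing


TCR_STRONG = GeneSignature(
    name="TCR.strong",
    genes=("ICOS", "IRF8", "STAT4", "TNFRSF4", "TNIP3"),
)

T_ACTIVATION = GeneSignature(
    name="T.activation",
    genes=("CD69", "IL2RA", "NR4A1", "TNFRSF9"),
    alias_map={"CD25": "IL2RA"},
)


def _normalize_to_million(
    matrix: ExpressionMatrix, expect_unit: str, out_unit: str, offset: float
) -> ExpressionMatrix:
    if matrix.unit != expect_unit:
        raise ValueError(f"expected unit {expect_unit!r}, got {matrix.unit!r}")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    colsums = matrix.data.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(
            f"zero column sum in sample(s): {', '.join(map(str, zero.index))}"
        )
    out = matrix.data.div(colsums, axis=1) * 1e6 + offset
    return ExpressionMatrix(out, out_unit)


def fpkm_to_tpm(matrix: ExpressionMatrix, offset: float = 0.01) -> ExpressionMatrix:
    """Convert FPKM to TPM: column-normalize to 1e6, then add ``offset``.

    TPM_gs = FPKM_gs / sum_g FPKM_gs * 1e6 + offset.  A zero-FPKM gene maps
    to exactly ``offset`` (0.01 by default).
    """
    return _normalize_to_million(matrix, "FPKM", "TPM", offset)


def counts_to_cpm(matrix: ExpressionMatrix, offset: float = 0.01) -> ExpressionMatrix:
    """Convert raw counts to CPM with the same post-normalization offset."""
    vals = matrix.data.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("counts matrix must be integer-valued")
    return _normalize_to_million(matrix, "counts", "CPM", offset)


def signature_score(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Geometric-mean signature score per sample.

    score_s = exp(mean over signature genes of ln(value_gs)); the input must
    be on a TPM or CPM scale with strictly positive values (guaranteed by
    the 0.01 offset).  Missing genes are a hard error unless
    ``allow_missing`` opts in to scoring on the intersection.

    Returns a ScoreTable DataFrame with columns sample_id, signature, score.
    """
    if matrix.unit not in ("TPM", "CPM"):
        raise ValueError("signature scores are defined on TPM or CPM matrices")
    present, missing = signature.resolve(matrix.data.index)
    if missing:
        if not allow_missing:
            raise KeyError(
                f"signature {signature.name!r} genes missing from matrix: "
                f"{sorted(missing)}"
            )
        if not present:
            raise KeyError(f"no genes of signature {signature.name!r} in matrix")
    sub = matrix.data.loc[present]
    if (sub.to_numpy() <= 0).any():
        raise ValueError("signature genes must have strictly positive values")
    scores = np.exp(np.log(sub).mean(axis=0))
    return pd.DataFrame(
        {
            "sample_id": matrix.samples,
            "signature": signature.name,
            "score": scores.to_numpy(dtype=float),
        }
    )
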