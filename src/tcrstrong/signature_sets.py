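"""DEG thresholding, ortholog mapping and four-set signature derivation.

Four up-regulated gene sets are intersected to derive the TCR.strong
signature:

* ``res`` — genes changing on-therapy specifically in melanoma patients who
  clinically respond to anti-PD1;
* ``ot`` — genes changing on-therapy regardless of response;
* ``strong4h`` — genes upregulated at 4 h in mouse T cells receiving a
  strong (80 ug) versus weak (0.8 ug) TCR stimulus;
* ``pd1`` — genes upregulated in mouse T cells re-activated for 4 h in the
  presence of anti-PD1 versus isotype.

Every responder-set gene is classified by its membership pattern in the
other three sets (groups I-VI); the derived signature is the union of group
I (in all four sets — pharmacodynamic correlates of anti-PD1) and group II
(responder-specific genes predicted by both mouse signatures).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .scoring import GeneSignature

__all__ = [
    "DEGThresholds",
    "HUMAN_PRESET",
    "MOUSE_STRONG_PRESET",
    "MOUSE_PD1_PRESET",
    "GROUPS",
    "threshold_deg",
    "map_orthologs",
    "OrthologResult",
    "classify_groups",
    "derive_signature",
    "read_deg_tsv",
]

GROUPS = ("I", "II", "III", "IV", "V", "VI", "unassigned")


@dataclass(frozen=True)
class DEGThresholds:
    """Strict DEG inclusion thresholds for one contrast.

    A gene is included when |log2fc| strictly exceeds ``lfc_min`` in the
    requested direction and padj is strictly below ``padj_max``; boundary
    values are excluded.
    """

    lfc_min: float
    padj_max: float
    direction: str = "up"

    def __post_init__(self) -> None:
        if not 0 < self.padj_max <= 1:
            raise ValueError("padj_max must be in (0, 1]")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


#: human melanoma contrasts (Res / OT): lfc > 0.5 and padj < 0.1
HUMAN_PRESET = DEGThresholds(lfc_min=0.5, padj_max=0.1)
#: mouse strong-vs-weak 4 h contrast: lfc > 1 and padj < 0.05
MOUSE_STRONG_PRESET = DEGThresholds(lfc_min=1.0, padj_max=0.05)
#: mouse anti-PD1 re-challenge contrast: padj < 0.05 only
MOUSE_PD1_PRESET = DEGThresholds(lfc_min=0.0, padj_max=0.05)


def read_deg_tsv(path) -> pd.DataFrame:
    """Read a DEG TSV with columns gene, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise ValueError(f"DEG table must have columns {sorted(required)}")
    return df


def threshold_deg(table: pd.DataFrame, thresholds: DEGThresholds) -> set[str]:
    """Apply strict DEG thresholds to a per-gene (gene, log2fc, padj) table."""
    if len(table) == 0:
        raise ValueError("DEG table is empty")
    if table["gene"].duplicated().any():
        dups = sorted(table.loc[table["gene"].duplicated(), "gene"].unique())
        raise ValueError(f"duplicate genes in DEG table: {dups}")
    padj = table["padj"]
    if ((padj < 0) | (padj > 1)).any():
        raise ValueError("padj values must lie in [0, 1]")
    if thresholds.direction == "up":
        keep = (table["log2fc"] > thresholds.lfc_min) & (padj < thresholds.padj_max)
    else:
        keep = (table["log2fc"] < -thresholds.lfc_min) & (padj < thresholds.padj_max)
    return set(table.loc[keep, "gene"])


# mouse -> human symbols that are not a plain case change
_ORTHOLOG_OVERRIDES: dict[str, str] = {
    "Tnfrsf4": "TNFRSF4",
    "Icos": "ICOS",
    "Irf8": "IRF8",
    "Tnip3": "TNIP3",
    "Stat4": "STAT4",
    "Il2ra": "IL2RA",
    "Nr4a1": "NR4A1",
    "Cd69": "CD69",
    "Tnfrsf9": "TNFRSF9",
    "Cd5": "CD5",
    "Gpr65": "GPR65",
    "Gcnt1": "GCNT1",
    "Ifng": "IFNG",
    "Gzmb": "GZMB",
    "Ctla4": "CTLA4",
}

# identifiers with no meaningful human symbol by casing: Riken clones,
# predicted Gm genes, antisense/opposite-strand transcripts
_UNMAPPABLE = re.compile(r"(^Gm\d+$)|(Rik$)|(os$)")


@dataclass(frozen=True)
class OrthologResult:
    mapped: frozenset[str]
    unmapped: tuple[str, ...]


def map_orthologs(
    mouse_genes: set[str], overrides: dict[str, str] | None = None
) -> OrthologResult:
    """Map mouse gene symbols to human symbols.

    Static rule for reproducibility: explicit overrides first, then plain
    uppercasing for ordinary title-case symbols.  Symbols that cannot be
    case-mapped (Riken clones, Gm predictions, antisense transcripts) are
    reported as unmapped, never silently dropped.
    """
    table = dict(_ORTHOLOG_OVERRIDES)
    if overrides:
        for k, v in overrides.items():
            if k in table and table[k] != v:
                raise ValueError(f"conflicting mapping for {k!r}: {table[k]} vs {v}")
            table[k] = v
    mapped: set[str] = set()
    unmapped: list[str] = []
    for g in sorted(mouse_genes):
        if g in table:
            mapped.add(table[g])
        elif _UNMAPPABLE.search(g):
            unmapped.append(g)
        else:
            mapped.add(g.upper())
    return OrthologResult(frozenset(mapped), tuple(unmapped))


def classify_groups(
    res: set[str], ot: set[str], strong4h: set[str], pd1: set[str]
) -> pd.Series:
    """Label every gene by its four-set membership pattern (groups I-VI).

    Genes outside the responder set are always ``unassigned``.  For a
    responder-set gene:

    I   in ot, strong4h and pd1      IV  in strong4h only
    II  in strong4h and pd1, not ot  V   in pd1 only
    III in ot and strong4h, not pd1  VI  in ot and pd1, not strong4h

    The remaining patterns (ot only, or none) stay ``unassigned``.
    """
    genes = sorted(res | ot | strong4h | pd1)
    labels = {}
    for g in genes:
        if g not in res:
            labels[g] = "unassigned"
            continue
        in_ot, in_4h, in_pd1 = g in ot, g in strong4h, g in pd1
        if in_ot and in_4h and in_pd1:
            labels[g] = "I"
        elif in_4h and in_pd1:
            labels[g] = "II"
        elif in_ot and in_4h:
            labels[g] = "III"
        elif in_4h:
            labels[g] = "IV"
        elif in_pd1 and not in_ot:
            labels[g] = "V"
        elif in_ot and in_pd1:
            labels[g] = "VI"
        else:
            labels[g] = "unassigned"
    out = pd.Series(labels, name="group", dtype="object")
    out.index.name = "gene"
    return out


def derive_signature(assignment: pd.Series, name: str = "TCR.strong-derived") -> GeneSignature:
    """Derive the strong-TCR-signal signature: union of groups I and II."""
    genes = sorted(assignment.index[assignment.isin(["I", "II"])])
    if not genes:
        raise ValueError(
            "no genes in groups I or II; review DEG thresholds and input sets"
        )
    return GeneSignature(name=name, genes=tuple(genes))
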