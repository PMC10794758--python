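"""The registry of the 16 named feature combinations and matrix assembly.

Five feature families exist: BP (base periodicity: peak, SNR), DP and TP
(di-/trinucleotide physicochemical energies: solvation, stacking, hbond),
DC and TC (PCA scores of di-/trinucleotide composition).  The classifier is
trained on one of 16 fixed concatenations of family subsets; for DC/TC the
subset is the top-variance principal components, for DP/TP the energy
triple truncated in (solvation, stacking, hbond) order, for BP always
(peak, snr).

The published combination table carries a few label slips (a row titled with
DP but abbreviated TPTC, a text "2 feature from TC" against arithmetic 13);
the registry follows the internally consistent reading: the count
arithmetic plus the abbreviations used in the reported metrics
(DPDC, TPTC, DCTC, DPTPDCTC).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

FAMILY_CAPACITY = {"BP": 2, "DP": 3, "TP": 3, "DC": 15, "TC": 15}


@dataclass(frozen=True)
class ComboSpec:
    """One named recipe: ordered (family, n_selected) parts."""

    name: str
    parts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for family, n in self.parts:
            if family not in FAMILY_CAPACITY:
                raise ValueError(f"unknown family {family!r}")
            if not 1 <= n <= FAMILY_CAPACITY[family]:
                raise ValueError(
                    f"{self.name}: {family} supports at most "
                    f"{FAMILY_CAPACITY[family]} features, asked {n}"
                )

    @property
    def total(self) -> int:
        return sum(n for _, n in self.parts)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.parts)


def _spec(name: str, *parts: tuple[str, int]) -> ComboSpec:
    return ComboSpec(name=name, parts=tuple(parts))


COMBO_REGISTRY: dict[str, ComboSpec] = {
    s.name: s
    for s in [
        _spec("DP", ("DP", 3)),
        _spec("TP", ("TP", 3)),
        _spec("DPTP", ("DP", 3), ("TP", 3)),
        _spec("DC", ("DC", 15)),
        _spec("TC", ("TC", 15)),
        _spec("BP", ("BP", 2)),
        _spec("BPDP", ("BP", 2), ("DP", 3)),
        _spec("BPTP", ("BP", 2), ("TP", 3)),
        _spec("BPDPTP", ("BP", 2), ("DP", 3), ("TP", 3)),
        _spec("BPDC", ("BP", 2), ("DC", 13)),
        _spec("BPTC", ("BP", 2), ("TC", 13)),
        _spec("BPDCTC", ("BP", 2), ("DC", 7), ("TC", 6)),
        _spec("DPDC", ("DP", 3), ("DC", 12)),
        _spec("TPTC", ("TP", 3), ("TC", 12)),
        _spec("DCTC", ("DC", 8), ("TC", 7)),
        _spec("DPTPDCTC", ("DP", 3), ("TP", 3), ("DC", 5), ("TC", 4)),
    ]
}

COMBO_NAMES = tuple(COMBO_REGISTRY)

# Column order within each family; DC/TC columns are already sorted by
# decreasing explained variance, so truncation keeps the top-variance PCs.
_FAMILY_COLUMN_PREFIX = {"DC": "dc_pc", "TC": "tc_pc"}


def get_combo(name: str) -> ComboSpec:
    try:
        return COMBO_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown combo {name!r}; valid names: {', '.join(COMBO_NAMES)}"
        ) from None


def assemble(
    combo: ComboSpec | str,
    feature_store: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Concatenate family subsets into one model-input matrix.

    ``feature_store`` maps family name to its full per-sequence matrix (all
    indexed by sequence id, identical order).  Returns the assembled matrix
    and a column->family provenance map.
    """
    if isinstance(combo, str):
        combo = get_combo(combo)
    blocks: list[pd.DataFrame] = []
    provenance: dict[str, str] = {}
    index = None
    for family, n in combo.parts:
        if family not in feature_store:
            raise ValueError(f"combo {combo.name}: family {family!r} missing from store")
        block = feature_store[family]
        if block.shape[1] < n:
            raise ValueError(
                f"combo {combo.name}: family {family} has {block.shape[1]} "
                f"columns, needs {n}"
            )
        if index is None:
            index = block.index
        elif not index.equals(block.index):
            raise ValueError(
                f"combo {combo.name}: row-id mismatch between families "
                f"({combo.parts[0][0]} vs {family})"
            )
        sub = block.iloc[:, :n]
        blocks.append(sub)
        provenance.update({c: family for c in sub.columns})
    matrix = pd.concat(blocks, axis=1)
    assert matrix.shape[1] == combo.total
    return matrix, provenance


def registry_table() -> pd.DataFrame:
    """The registry as a printable table (name, parts, total columns)."""
    rows = [
        (
            s.name,
            " + ".join(f"{n} {fam}" for fam, n in s.parts),
            s.total,
        )
        for s in COMBO_REGISTRY.values()
    ]
    return pd.DataFrame(rows, columns=["combo", "parts", "n_features"])
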