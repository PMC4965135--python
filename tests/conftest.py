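"""Shared fixtures: case-study gene lists and small synthetic configs."""

from __future__ import annotations

import pytest

from mirsig.synthetic import SyntheticConfig

# Case-study signature network: the two top hub genes of the miR-132
# consensus-target network with their reported interaction partners.
KRAS_PARTNERS = [
    "ARID1A", "BRCA1", "DNMT3A", "EGR1", "FOXO3", "FRS2", "GNA12", "HMGA2",
    "MAPK1", "PTCH1", "PXN", "SGK3", "SIRT1", "USP9X", "WT1", "YWHAG",
]
MAPK1_PARTNERS = [
    "BRCA1", "CITED2", "DUSP9", "EGR1", "FOXO3", "FRS2", "GATA2", "GNA12",
    "KRAS", "NET1", "PEA15", "PXN", "SGK3", "SPRY1", "YWHAG",
]

# Case-study significant pathways with their reported member genes among
# the miR-132 consensus targets.
PATHWAY_MEMBERS = {
    "neurotrophin_signaling": {"MAPK1", "YWHAG", "KRAS", "FOXO3", "FRS2"},
    "mapk_signaling": {"MAPK1", "KRAS", "NLK", "GNA12", "DUSP9"},
    "vegf_signaling": {"MAPK1", "KRAS", "PXN"},
    "adherens_junction": {"MAPK1", "NLK", "TCF7L2"},
}

# The 59-gene overlap signature: genes both disease-associated in the
# literature screen and nominated as miR-132 targets by the consensus vote.
OVERLAP_59 = [
    "SIRT1", "SPRY1", "DPYSL3", "NOVA1", "SOX4", "PFTK1", "SEC62", "MAPK1",
    "PXN", "PCDH10", "BTG2", "HMGA2", "YWHAG", "PEA15", "HN1", "SGK3",
    "LIN28B", "SOX6", "ARID2", "ZEB2", "DUSP9", "SOX2", "FOXO3", "TLN2",
    "CPEB4", "TCF7L2", "DNMT3A", "MIB1", "WT1", "LIN9", "CCNG1", "KRAS",
    "PIK3IP1", "GATA2", "ARID1A", "DYNLL2", "EGR1", "TTK", "IDS", "MAOA",
    "BTBD7", "PTCH1", "USP9X", "CYLD", "SOD2", "ST18", "EIF2C2", "BRCA1",
    "GNA12", "NLK", "GOLM1", "DACH1", "ACSL4", "FRS2", "RTN4", "SLC2A1",
    "NET1", "CITED2", "NFE2L2",
]


@pytest.fixture
def small_config() -> SyntheticConfig:
    """A fast, small synthetic study for unit tests."""
    return SyntheticConfig(
        n_articles=200,
        gene_universe=tuple(f"HG{i}" for i in range(1, 31)),
        planted_assoc={f"HG{i}": 6.0 for i in range(1, 6)},
        planted_targets=tuple(f"HG{i}" for i in range(3, 13)),
        pathway_sizes=(5, 6),
        planted_pathway_membership={"PW1": frozenset({"HG3", "HG4", "HG5"})},
        planted_edges=(("HG3", "PPrel", "HG4"), ("HG4", "GErel", "HG5")),
        seed=11,
    )
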