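import numpy as np
import pytest

from phosmotif import (
    GroupIndex,
    GroupMember,
    OrthologGroup,
    SpeciesLadder,
    generate_bundle,
)


@pytest.fixture(scope="session")
def ladder():
    return SpeciesLadder.default()


@pytest.fixture(scope="session")
def bundle():
    """Default study conditions: 9 species, 200 families, 4 planted motifs
    (one yeast-to-human, three sigmoid) x 30 instances, noise 0.05."""
    return generate_bundle(seed=101)


def make_group(group_id, seqs):
    """Build an OrthologGroup from {species: (protein_id, aligned_seq)}."""
    return OrthologGroup(
        group_id,
        tuple(GroupMember(sp, pid, seq) for sp, (pid, seq) in seqs.items()),
    )


@pytest.fixture(scope="session")
def toy_ladder():
    return SpeciesLadder(("yst", "wrm", "fly", "hsa"), (0.3, 0.3, 0.3))


@pytest.fixture(scope="session")
def toy_groups():
    """Three hand-built groups; one phosphosite at position 3 of each.

    g1: anchor S conserved as T in yeast (distal) -> closure makes every
        species conserved.
    g2: anchor conserved nowhere outside human.
    g3: anchor conserved in fly only; worm member has a gap at the column.
    Hand-counted rates (yst, wrm, fly, hsa) = (1/3, 1/3, 2/3, 1).
    """
    return [
        make_group("g1", {
            "hsa": ("p1", "AKSDE"),
            "fly": ("p1_fly", "AKSDE"),
            "wrm": ("p1_wrm", "AKADE"),
            "yst": ("p1_yst", "AKTDE"),
        }),
        make_group("g2", {
            "hsa": ("p2", "MKSRR"),
            "fly": ("p2_fly", "MKARR"),
            "wrm": ("p2_wrm", "MKARR"),
            "yst": ("p2_yst", "MKARR"),
        }),
        make_group("g3", {
            "hsa": ("p3", "PPSYQ"),
            "fly": ("p3_fly", "PPSYQ"),
            "wrm": ("p3_wrm", "PP-YQ"),
            "yst": ("p3_yst", "PPAYQ"),
        }),
    ]


@pytest.fixture(scope="session")
def toy_index(toy_groups):
    return GroupIndex(toy_groups)


@pytest.fixture(scope="session")
def toy_sites():
    return [("p1", 3), ("p2", 3), ("p3", 3)]
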