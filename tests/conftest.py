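import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix
from barcodekit.io import BarcodeRecord


def record(
    id_: str,
    seq: str,
    species: str = "spA",
    genus: str = "gA",
    family: str = "fA",
    higher_taxon: str = "tA",
) -> BarcodeRecord:
    return BarcodeRecord(
        id=id_, species=species, genus=genus, family=family,
        higher_taxon=higher_taxon, sequence=seq,
    )


def matrix_from_array(ids, d) -> DistanceMatrix:
    """DistanceMatrix wrapper around a plain symmetric array (full overlap)."""
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(
        ids=list(ids), d=d,
        overlap=np.full_like(d, 10_000, dtype=np.int64), min_overlap=1,
    )


@pytest.fixture
def two_genus_records():
    """Two species per genus, two genera, strong gap, no ambiguity codes.

    Sequences are 20 bp; conspecific pairs differ at 1 site (5%),
    congeneric heterospecific pairs at ~8 sites, cross-genus more.
    """
    base = "ACGTACGTACGTACGTACGT"

    def mutate(s, positions, to="T"):
        out = list(s)
        for p in positions:
            out[p] = to if out[p] != to else "A"
        return "".join(out)

    sp1 = base
    sp2 = mutate(base, range(0, 8))
    sp3 = mutate(base, range(8, 16), to="C")
    sp4 = mutate(sp3, range(0, 8))
    recs = [
        record("a1", sp1, species="spA", genus="gA"),
        record("a2", mutate(sp1, [19]), species="spA", genus="gA"),
        record("b1", sp2, species="spB", genus="gA"),
        record("b2", mutate(sp2, [19]), species="spB", genus="gA"),
        record("c1", sp3, species="spC", genus="gB"),
        record("c2", mutate(sp3, [19]), species="spC", genus="gB"),
        record("d1", sp4, species="spD", genus="gB"),
    ]
    return recs
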