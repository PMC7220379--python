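import numpy as np
import pytest

import scnahet as s


@pytest.fixture(scope="session")
def small_scheme():
    """Two toy chromosomes, 30 bins total."""
    return s.make_bin_scheme(30, {"chr1": 20_000_000, "chr2": 10_000_000})


@pytest.fixture(scope="session")
def genome_scheme():
    """A down-scaled human genome: 800 bins over 23 female chromosomes."""
    return s.make_bin_scheme(800)


def two_clone_config(**overrides):
    """A biopsy with a dominant clone and a child sub-clone carrying a
    focal amplification and a chromosome-13 loss."""
    clones = [
        s.CloneSpec("A", 0.45, events=[
            s.CNAEvent("chr8", 46_000_000, 146_000_000, delta=1, name="8q+"),
            s.CNAEvent("chr18", 1, 15_000_000, delta=-1, name="18p-")]),
        s.CloneSpec("B", 0.30, parent="A", events=[
            s.CNAEvent("chr19", 30_000_000, 38_000_000, target_cn=24,
                       name="CCNE1amp"),
            s.CNAEvent("chr13", 1, 115_000_000, delta=-1, name="13-")]),
    ]
    base = dict(clones=clones, n_cells=60, reads_per_cell=500_000, n_bins=800,
                n_t_cells=6, n_b_cells=2, n_pseudo_diploid=2, x_loss_frac=0.3)
    base.update(overrides)
    return s.SimConfig(**base)


@pytest.fixture(scope="session")
def two_clone_sim():
    return s.simulate_sample(two_clone_config(), seed=3)
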