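import numpy as np
import pytest

from gnome import genome


@pytest.fixture
def sphere5() -> genome.NucleusShape:
    return genome.NucleusShape.sphere(5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_specs() -> list[genome.BeadSpec]:
    """Two 3-bead diploid chromosome pairs with a few contacts."""
    specs = []
    for chrom in ("chr1_A", "chr1_B", "chr2_A", "chr2_B"):
        for k in range(3):
            specs.append(
                genome.BeadSpec(
                    chrom=chrom,
                    start=k * 1_000_000,
                    end=(k + 1) * 1_000_000,
                    bead_id=f"{chrom}.{k}",
                    periphery=(k == 2),
                )
            )
    by_id = {s.bead_id: s for s in specs}
    from dataclasses import replace

    by_id["chr1_A.0"] = replace(by_id["chr1_A.0"], edges=frozenset({"chr2_A.1"}))
    by_id["chr1_B.2"] = replace(by_id["chr1_B.2"], edges=frozenset({"chr2_B.0"}))
    return list(by_id.values())


@pytest.fixture(scope="session")
def small_specs() -> list[genome.BeadSpec]:
    """~200-bead diploid synthetic genome used for solver-scale tests."""
    cfg = genome.GenomeConfig(
        total_bp=400_000_000,
        chrom_weights={f"c{i}": 1.0 for i in range(4)},
        diploid=True,
        tad_bp_min=1_000_000,
        tad_bp_max=3_000_000,
    )
    return genome.synthesize_genome(cfg, seed=5)


@pytest.fixture(scope="session")
def small_conformation(small_specs) -> genome.GenomeConformation:
    nuc = genome.NucleusShape.sphere(5.0)
    return genome.build_initial_conformation(small_specs, nuc, seed=9)
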