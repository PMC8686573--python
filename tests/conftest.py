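import numpy as np
import pandas as pd
import pytest

from chronokit import ScreenData, SimulationScenario, simulate_screen


def make_toy_screen() -> ScreenData:
    """3 replicates x 8 guides (4 genes, 2 guides each), one batch, 2 pDNA rows."""
    guides = [f"G{g}_sg{k}" for g in range(4) for k in range(2)]
    counts = pd.DataFrame(
        [
            [100, 120, 80, 90, 110, 100, 95, 105],
            [100, 100, 100, 100, 100, 100, 100, 100],
            [50, 60, 200, 40, 80, 90, 100, 110],
            [90, 110, 85, 95, 105, 95, 100, 120],
        ],
        index=["pdna_a", "pdna_b", "rep1", "rep2"],
        columns=guides,
        dtype=float,
    )
    sequence_map = pd.DataFrame(
        {
            "sequence_ID": ["pdna_a", "pdna_b", "rep1", "rep2"],
            "cell_line_name": ["pDNA", "pDNA", "lineA", "lineA"],
            "pDNA_batch": ["b0", "b0", "b0", "b0"],
            "days": [0.0, 0.0, 14.0, 14.0],
        }
    )
    guide_map = pd.DataFrame(
        {"sgrna": guides, "gene": [f"G{g}" for g in range(4) for _ in range(2)]}
    )
    return ScreenData(counts=counts, sequence_map=sequence_map, guide_map=guide_map)


@pytest.fixture
def toy_screen() -> ScreenData:
    return make_toy_screen()


@pytest.fixture(scope="session")
def small_sim():
    """Small noisy simulated screen with truth, shared across tests."""
    scenario = SimulationScenario(
        name="unit", n_lines=3, n_genes=60, guides_per_gene=4, n_replicates=1,
        time_points=(7.0, 14.0), depth=400.0, seed=7,
    )
    return simulate_screen(scenario)


@pytest.fixture(scope="session")
def noise_free_sim():
    """Deterministic screen (counts equal NB2 means) with perfect reagents."""
    scenario = SimulationScenario(
        name="unit_exact", n_lines=3, n_genes=60, guides_per_gene=4,
        n_replicates=1, time_points=(7.0, 14.0, 21.0), depth=500.0, seed=3,
        noise=False, guide_efficacy_beta=(1e6, 1.0), cell_efficacy_range=(1.0, 1.0),
    )
    return simulate_screen(scenario)


def write_screen(tmp_path, data: ScreenData):
    counts = tmp_path / "counts.csv"
    seqmap = tmp_path / "sequence_map.csv"
    guides = tmp_path / "guide_map.csv"
    data.counts.to_csv(counts)
    data.sequence_map.to_csv(seqmap, index=False)
    data.guide_map.to_csv(guides, index=False)
    return counts, seqmap, guides
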