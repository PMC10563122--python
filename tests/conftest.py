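import pandas as pd
import pytest

import maitseq as m


@pytest.fixture(scope="session")
def panel():
    return m.build_reference(seed=1)


def _run(panel, **overrides):
    defaults = dict(
        n_subjects={"HD": 1, "PR": 1, "EC": 1},
        cells_per_subject_condition=30,
        reads_per_chain_median=25.0,
        reads_per_phenotype_median=15.0,
        seed=3,
    )
    defaults.update(overrides)
    cfg = m.SimulationConfig(**defaults)
    cells = m.simulate_repertoire(panel, cfg)
    reads, reads_truth = m.simulate_reads(cells, panel, cfg)
    called, stats = m.call_cells(reads, panel, m.sample_sheet(cells))
    truth = m.truth_cells_frame(cells)
    return dict(config=cfg, cells=cells, reads=reads, reads_truth=reads_truth,
                called=called, stats=stats, truth=truth)


@pytest.fixture(scope="session")
def noisy_run(panel):
    """180-cell simulation at the default error/contamination rates."""
    return _run(panel)


@pytest.fixture(scope="session")
def clean_run(panel):
    """Same simulation with zero errors and zero contamination."""
    return _run(panel, error_rate=0.0, contamination_rate=0.0)


def concordant_first_calls(merged_row) -> bool:
    """Called beta and first alpha (V, J, CDR3aa) match the truth cell.

    The called first alpha may be either of a dual-alpha cell's chains
    (read sampling decides which one dominates the well).
    """
    r = merged_row
    truth_alphas = {
        (r["trav_t"], r["traj_t"], r["cdr3a_aa_t"]),
        (r["trav2_t"], r["traj2_t"], r["cdr3a2_aa_t"]),
    }
    return (r["cdr3b_aa"] == r["cdr3b_aa_t"]
            and r["trbv"] == r["trbv_t"] and r["trbj"] == r["trbj_t"]
            and (r["trav"], r["traj"], r["cdr3a_aa"]) in truth_alphas)


def merge_with_truth(called: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    return called.merge(truth, on="cell_id", suffixes=("", "_t"))
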