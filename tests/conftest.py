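import pandas as pd
import pytest

from netprism import annotation, simulate as sim
from netprism.annotation import GeneModel


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    """One full simulated library (default study conditions, fixed seed)."""
    outdir = tmp_path_factory.mktemp("sim_total")
    model, truth, paths = sim.simulate(str(outdir), preset="total", seed=1)
    return model, truth, paths


@pytest.fixture(scope="session")
def sim_truth_table(sim_run):
    _, _, paths = sim_run
    return pd.read_csv(paths["truth"], sep="\t")


@pytest.fixture(scope="session")
def sim_terminals(sim_run):
    model, _, _ = sim_run
    return annotation.terminal_nucleotides(model.genes)


def make_gene(gene_id="g1", chrom="chr1", strand="+", exons=((100, 200), (300, 400))):
    ex = [tuple(e) for e in exons]
    start = min(s for s, _ in ex)
    end = max(e for _, e in ex)
    return GeneModel(gene_id, chrom, strand, start, end, ex)
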