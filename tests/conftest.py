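import numpy as np
import pytest

from gliosplice import PipelineConfig, SpliceEvent


@pytest.fixture
def config():
    return PipelineConfig()


def make_event(event_id="ev1", gene="GENE1", event_class="CE", chrom="chr1",
               start=100, end=200, strand="+", p_value=0.01,
               inclusion_reads=20, exclusion_reads=20, psi_treated=0.8,
               psi_control=0.5):
    return SpliceEvent(event_id=event_id, gene=gene, event_class=event_class,
                       chrom=chrom, start=start, end=end, strand=strand,
                       p_value=p_value, inclusion_reads=inclusion_reads,
                       exclusion_reads=exclusion_reads,
                       psi_treated=psi_treated, psi_control=psi_control)


def random_events(n, seed):
    """Events spanning both sides of every significance threshold."""
    rng = np.random.default_rng(seed)
    events = []
    for i in range(n):
        inc = int(rng.integers(0, 30))
        exc = int(rng.integers(0, 30))
        psi_c = float(rng.uniform(0, 1))
        dpsi = float(rng.uniform(-0.3, 0.3))
        psi_t = float(np.clip(psi_c + dpsi, 0, 1))
        events.append(SpliceEvent(
            event_id=f"r{i}", gene=f"G{i}", event_class="CE", chrom="chr1",
            start=1000 * i + 100, end=1000 * i + 300, strand="+",
            p_value=float(rng.uniform(0, 0.12)), inclusion_reads=inc,
            exclusion_reads=exc, psi_treated=psi_t, psi_control=psi_c))
    return events
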