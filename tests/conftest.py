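"""Shared fixtures: small synthetic experiments built at test time."""

import numpy as np
import pytest

from costimsplice import SimulationConfig, simulate_counts, simulate_genome, simulate_truth


@pytest.fixture(scope="session")
def small_sim():
    """A 150-event mixed-class experiment at default settings."""
    cfg = SimulationConfig(n_events=150, seed=11)
    truth = simulate_truth(cfg)
    counts = simulate_counts(truth, cfg)
    return cfg, truth, counts


@pytest.fixture(scope="session")
def genome_sim():
    """A 120-event experiment with a planted TGCATG motif and genome."""
    cfg = SimulationConfig(n_events=120, seed=7)
    truth = simulate_truth(cfg)
    genome, annotations = simulate_genome(truth, "TGCATG", 1.0, 0.0, cfg)
    return cfg, truth, genome, annotations


def make_window_set(rng, n, motif=None, motif_fraction=0.0,
                    up_len=220, exon_len=120, dn_len=243, prefix="w"):
    """Random-sequence windows with a motif planted in a fraction of them."""
    from costimsplice.types import SequenceWindow

    bases = np.array(list("ACGT"))
    out = []
    for i in range(n):
        up = "".join(rng.choice(bases, up_len))
        ex = "".join(rng.choice(bases, exon_len))
        dn = "".join(rng.choice(bases, dn_len))
        if motif is not None and rng.random() < motif_fraction:
            pos = int(rng.integers(0, dn_len - len(motif)))
            dn = dn[:pos] + motif + dn[pos + len(motif):]
        out.append(SequenceWindow(f"{prefix}{i}", up, ex, dn, False))
    return out
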