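"""Shared fixtures: small simulated datasets and random-CDS helpers."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Data.CodonTable import unambiguous_dna_by_id

from insite import SimulationSpec, simulate_coverage, simulate_genome

#: sense codons of the bacterial code, for building random valid payloads
_TABLE11 = unambiguous_dna_by_id[11]
SENSE_CODONS = sorted(_TABLE11.forward_table)
STOP_CODONS = sorted(_TABLE11.stop_codons)


def random_payload(rng: np.random.Generator, n_codons: int = 60) -> str:
    """A random valid CDS: ATG + n sense codons + one stop."""
    body = "".join(
        SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)
    )
    stop = STOP_CODONS[int(rng.integers(0, len(STOP_CODONS)))]
    return "ATG" + body + stop


def random_protein(rng: np.random.Generator, n: int) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(0, len(aas), size=n))


# --- independent terminator oracle ----------------------------------------
# A deliberately dumb re-derivation of the scoring scheme: enumerate every
# (start, stem_len, loop_len) triple and keep the best total score. Shares no
# code with the scanner.

_ORACLE_PAIRS = {
    "GC": 3.0, "CG": 3.0, "AT": 2.0, "TA": 2.0, "GT": 1.0, "TG": 1.0,
}
_ORACLE_TAIL_W = [2.0, 1.5, 1.5, 1.0, 1.0, 0.5, 0.5, 0.5]


def brute_force_best_terminator(
    seq: str,
    stem_range=(4, 20),
    loop_range=(3, 9),
    h_min: float = 8.0,
    t_min: float = 3.0,
) -> float | None:
    """Best total score over all exact-pairing hairpin+tract configurations,
    or None when no configuration qualifies."""
    n = len(seq)
    best = None
    for s in range(n):
        for k in range(stem_range[0], stem_range[1] + 1):
            for l in range(loop_range[0], loop_range[1] + 1):
                if s + 2 * k + l > n:
                    continue
                score = 0.0
                ok = True
                for j in range(k):
                    w = _ORACLE_PAIRS.get(seq[s + j] + seq[s + 2 * k + l - 1 - j])
                    if w is None:
                        ok = False
                        break
                    score += w
                if not ok:
                    continue
                hp = score - 1.0 * (l - loop_range[0])
                if hp < h_min:
                    continue
                tail = seq[s + 2 * k + l : s + 2 * k + l + 8]
                tail = (tail + "N" * 8)[:8]
                t = sum(w for w, b in zip(_ORACLE_TAIL_W, tail) if b == "T")
                if t < t_min:
                    continue
                total = hp + t
                if best is None or total > best:
                    best = total
    return best


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """A scaled-down benchmark: 2 true sites, one decoy of each class."""
    return SimulationSpec(
        genome_len=40_000,
        n_genes=12,
        n_true_sites=2,
        n_decoys={"no_terminator": 1, "read_through": 1, "tandem": 1, "divergent": 1},
        n_conditions=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_spec):
    genome, annotation, manifest = simulate_genome(small_spec)
    tracks = simulate_coverage(manifest, small_spec)
    return genome, annotation, manifest, tracks
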