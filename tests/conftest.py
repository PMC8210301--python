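import numpy as np
import pytest

from ribometh import ReferenceSet, SimTruth, simulate_reference


@pytest.fixture
def toy_refs():
    """Two small molecules plus one SNORD, RNA alphabet."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGU"))
    seqs = {
        "SSU": "".join(rng.choice(bases, size=120)),
        "LSU": "".join(rng.choice(bases, size=150)),
        "SNORD901": "".join(rng.choice(bases, size=80)),
    }
    return ReferenceSet(molecules=seqs, snords={"SNORD901": seqs["SNORD901"]})


@pytest.fixture(scope="session")
def sim_setup():
    """Standard simulated study: 2000-nt reference, 40 sites, f ~ U(0,1)."""
    refs, sites = simulate_reference(2000, 40, seed=11)
    rng = np.random.default_rng(12)
    f = {s.site_id: float(rng.uniform(0.0, 1.0)) for s in sites}
    truth = SimTruth(sites=sites, f=f, lam=500.0, seed=13)
    return refs, sites, truth


def write_sam(path, refs, records):
    """Write a minimal SAM: records are (name, flag, molecule, pos1, cigar, seq)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for m, s in refs.molecules.items():
            fh.write(f"@SQ\tSN:{m}\tLN:{len(s)}\n")
        for name, flag, mol, pos, cigar, seq in records:
            fh.write(f"{name}\t{flag}\t{mol}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n")
    return path
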