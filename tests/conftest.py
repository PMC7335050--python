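from __future__ import annotations

import numpy as np
import pytest

from groovemapper.csp import CSPProfile, CSPRecord, _set_threshold


def write_ca_pdb(path, residue_ids, chain="A", seed=0, extra_lines=()):
    """Write a minimal single-model CA-only PDB with the given residue numbers."""
    rng = np.random.default_rng(seed)
    lines = []
    serial = 1
    for rid in residue_ids:
        x, y, z = rng.uniform(-30, 30, 3)
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA {chain}{rid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.extend(extra_lines)
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def make_profile(assigned, perturbed, klass="shifted"):
    """Build a classified CSPProfile directly from residue sets (test helper)."""
    records = []
    for rid in sorted(assigned):
        hit = rid in perturbed
        records.append(
            CSPRecord(
                residue_id=rid,
                delta_dH=0.05 if hit else 0.0,
                delta_dN=0.2 if hit else 0.0,
                csp=0.04 if hit else 0.0,
                intensity_ratio=0.05 if (hit and klass == "attenuated") else 1.0,
                klass=klass if hit else "unperturbed",
            )
        )
    profile = CSPProfile(records=records, noise_floor=0.1)
    _set_threshold(profile)
    return profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
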