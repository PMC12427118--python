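"""Shared fixtures: idealized structures, clash profile, synthetic genome.

Heavy objects are session-scoped; everything is generated at test time
from fixed seeds (no stored data files).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nucsteric.matching import ThresholdPair, classify_expression, matched_experiment
from nucsteric.nome import (
    complement_hndr,
    define_regions,
    detect_lndr,
    filter_coverage,
)
from nucsteric.simulate import (
    SimConfig,
    simulate_annotation,
    simulate_methylation,
    simulate_tpm,
)
from nucsteric.structures import build_idealized_nucleosome, build_idealized_probe
from nucsteric.superimpose import compute_clash_profile

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# --- structures -----------------------------------------------------------

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C1' DA  B   1       2.300  -1.200   0.750  1.00  0.00           C
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


@pytest.fixture(scope="session")
def nucleosome():
    return build_idealized_nucleosome(seed=1)


@pytest.fixture(scope="session")
def probe():
    return build_idealized_probe(seed=1)


@pytest.fixture(scope="session")
def clash_profile(nucleosome, probe):
    return compute_clash_profile(nucleosome, probe)


# --- synthetic genome ------------------------------------------------------


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=3)


@pytest.fixture(scope="session")
def sim_bundle(sim_cfg, clash_profile):
    """Full synthetic dataset plus NDR calls and regions (seed 3)."""
    genes, sizes = simulate_annotation(sim_cfg)
    tpm = simulate_tpm(sim_cfg, genes)
    sim = simulate_methylation(sim_cfg, genes, sizes, tpm, profile=clash_profile)
    gch = filter_coverage(sim["gch"])
    hcg = filter_coverage(sim["hcg"])
    lndrs, qc = detect_lndr(gch, sizes)
    hndrs = complement_hndr(lndrs, sizes)
    regions = define_regions(genes, sizes)
    return {
        "cfg": sim_cfg,
        "genes": genes,
        "sizes": sizes,
        "tpm": tpm,
        "gch": gch,
        "hcg": hcg,
        "planted": sim["planted_lndrs"],
        "hcg_truth": sim["hcg_truth"],
        "lndrs": lndrs,
        "hndrs": hndrs,
        "ndrs": pd.concat([lndrs, hndrs], ignore_index=True),
        "regions": regions,
        "qc": qc,
    }


@pytest.fixture(scope="session")
def effect_matches(sim_bundle, clash_profile):
    """Experimental + randomized match-scores at c5m0 on the synthetic set."""
    expr = classify_expression(sim_bundle["tpm"])
    return matched_experiment(
        sim_bundle["ndrs"],
        sim_bundle["regions"],
        sim_bundle["hcg"],
        clash_profile,
        thresholds=[ThresholdPair(5, 0)],
        expression_class=expr,
        seed=11,
    )


def jaccard_per_planted(lndrs: pd.DataFrame, planted: pd.DataFrame) -> list[float]:
    """Per-planted-region Jaccard between the call union and the plant."""
    out = []
    for _, p in planted.iterrows():
        ov = lndrs[
            (lndrs["chrom"] == p["chrom"])
            & (lndrs["start"] < p["end"])
            & (lndrs["end"] > p["start"])
        ]
        if not len(ov):
            out.append(0.0)
            continue
        inter = sum(
            min(p["end"], e) - max(p["start"], s)
            for s, e in zip(ov["start"], ov["end"])
        )
        union = (p["end"] - p["start"]) + int((ov["end"] - ov["start"]).sum()) - inter
        out.append(inter / union)
    return out
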