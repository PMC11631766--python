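import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zfrec import design as dz
from zfrec import simulate as sim

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_lox() -> dz.LoxSite:
    # 13 + 8 + 13 synthetic lox-like site (the published sites are not printed
    # anywhere; all lox sequences are inputs)
    return dz.LoxSite("loxSyn", "ATAACTTCGTATA", "GCATACAT", "TATACGAAGTTAT")


@pytest.fixture(scope="session")
def toy_motif() -> dz.ZfMotif:
    return dz.ZfMotif("zifSyn", "GCGTGGGCG")


@pytest.fixture(scope="session")
def toy_cds():
    """(recombinase CDS 343 codons incl. stop, ZF domain CDS 90 codons, no
    start/stop — an internal domain, not a standalone ORF)."""
    rng = np.random.default_rng(11)
    rec = sim.random_cds(343, rng)
    zf = sim.random_cds(91, rng, stop=False)[3:]
    if zf.startswith("ATG"):
        zf = "GCT" + zf[3:]
    return rec, zf


@pytest.fixture(scope="session")
def toy_backbone():
    rng = np.random.default_rng(12)
    backbone = (
        sim.random_sequence(120, rng)
        + "<SITE1><INTERSITE><SITE2>"
        + sim.random_sequence(60, rng)
        + "<CDS>"
        + sim.random_sequence(80, rng)
    )
    intersite = sim.random_sequence(250, rng)
    return backbone, intersite


def build_screen(
    lox,
    motif,
    rec_cds,
    zf_cds,
    backbone,
    intersite,
    fusions,
    sites,
):
    """Reference pairs + amplicon list for a fusion × site grid."""
    pairs = {}
    amplicons = []
    for f in fusions:
        cds = dz.build_fusion_cds(rec_cds, zf_cds, f)
        for s in sites:
            site = dz.build_target_site(s)
            vid = f"{f.key}|{s.key}"
            unrec, rec = dz.build_reference_pair(backbone, site, cds, intersite, vid)
            pairs[vid] = (unrec, rec)
            amplicons += [unrec, rec]
    return pairs, amplicons


@pytest.fixture(scope="session")
def small_screen(toy_lox, toy_motif, toy_cds, toy_backbone):
    """10 terminal fusion variants on one flanked site, with references."""
    rec_cds, zf_cds = toy_cds
    backbone, intersite = toy_backbone
    fusions = dz.enumerate_fusion_library(
        "brec",
        [dz.FusionMode.N_TERMINAL, dz.FusionMode.C_TERMINAL],
        linker_grid=[2, 4, 6, 8, 10],
    )
    sites = [
        dz.TargetSiteDesign(
            lox=toy_lox, motif=toy_motif, spacing_bp=5, orientation=dz.Orientation.A
        )
    ]
    pairs, amplicons = build_screen(
        toy_lox, toy_motif, rec_cds, zf_cds, backbone, intersite, fusions, sites
    )
    return {
        "fusions": fusions,
        "sites": sites,
        "pairs": pairs,
        "amplicons": amplicons,
    }
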