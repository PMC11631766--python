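"""Enumerate a fusion screen's design space and synthesize reference amplicons.

Builds the terminal-fusion screen grammar (N/C terminus x 6 GGS linker
lengths, 11 spacings x 2 motif orientations + the bare lox site), reports
the combination count, and assembles one UNREC/REC reference pair.
"""

import numpy as np

from zfrec import design as dz
from zfrec.simulate import random_cds, random_sequence

lox = dz.LoxSite("loxSyn", "ATAACTTCGTATA", "GCATACAT", "TATACGAAGTTAT")
motif = dz.ZfMotif("zifSyn", "GCGTGGGCG")

sites = dz.enumerate_target_library(lox, motif, range(11))
terminal = dz.enumerate_fusion_library(
    "brec", [dz.FusionMode.N_TERMINAL, dz.FusionMode.C_TERMINAL]
)
insertional = dz.enumerate_fusion_library("brec", [dz.FusionMode.INSERTIONAL])

print(f"target-site designs: {len(sites)} (11 spacings x 2 orientations + unflanked)")
print(f"terminal fusion designs: {len(terminal)}; insertional: {len(insertional)}")
print(f"terminal screen size: {dz.count_design_space(terminal, sites)} combinations")
print(f"insertional screen size: {dz.count_design_space(insertional, sites)} combinations")

design = dz.TargetSiteDesign(lox=lox, motif=motif, spacing_bp=5,
                             orientation=dz.Orientation.A)
site = dz.build_target_site(design)
print(f"\ncomposite site, spacing 5: {len(site.sequence)} nt "
      f"(34 lox + 2 x (9 motif + 5 pad))")
print(f"protein-bound bases (lox + both motifs): {dz.bound_site_length(design)}")

rng = np.random.default_rng(0)
rec_cds = random_cds(343, rng)
zf_cds = random_cds(91, rng, stop=False)[3:]
fusion = dz.FusionDesign("brec", dz.FusionMode.INSERTIONAL, 8, 8, insertion_junction=278)
cds = dz.build_fusion_cds(rec_cds, zf_cds, fusion)
print(f"\ninsertional fusion CDS ({fusion.key}): {len(cds)} nt, in frame: {len(cds) % 3 == 0}")

backbone = (random_sequence(100, rng) + "<SITE1><INTERSITE><SITE2>"
            + random_sequence(50, rng) + "<CDS>" + random_sequence(50, rng))
unrec, rec = dz.build_reference_pair(backbone, site, cds, random_sequence(250, rng),
                                     f"{fusion.key}|{design.key}")
print(f"UNREC amplicon: {len(unrec.sequence)} nt with {len(unrec.annotations['target_site'])} "
      f"target sites; REC: {len(rec.sequence)} nt with 1 site")
print("length difference = intersite + one full site:",
      len(unrec.sequence) - len(rec.sequence))
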