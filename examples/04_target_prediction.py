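"""Find and score a miRNA target site in a 3'UTR.

A candidate site must pair the seed (mature positions 2-8) with perfect
Watson-Crick complementarity; G-U wobbles are allowed, and counted, only in
the 3' supplementary region. Each site is scored by
ddG = dG_duplex + dG_open: the hybridization free energy of the miRNA with
the site region, plus the non-negative cost of opening the site's local
secondary structure (computed from McCaskill partition functions over the
site +/- 70 nt). More negative ddG means a stronger predicted interaction.
"""

from mirlearn import (
    EnergyModel,
    MIR137_MATURE,
    duplex_energy,
    generate_target_utr,
    predict_targets,
    scan_utr,
)

model = EnergyModel.default()

# a synthetic UTR carrying one planted site (2 G-U wobbles outside the seed)
planted = generate_target_utr(MIR137_MATURE, flank_len=60, rng_seed=1)
print(f"UTR of {len(planted.utr)} nt; planted site at "
      f"[{planted.site_start}, {planted.site_end}), {planted.n_wobbles} wobbles")

sites = scan_utr(planted.utr, MIR137_MATURE)
print(f"seed scan finds {len(sites)} site(s); "
      f"seed window [{sites[0].utr_start}, {sites[0].utr_end})")

# pairing diagram: mature position -> UTR position, pair type
print("\npairing map (mature pos, UTR pos, type):")
row = "  " + " ".join(
    f"{p}:{t}" for p, _q, t in sites[0].pairing_map if t != "none"
)
print(row)

scores = predict_targets(MIR137_MATURE, planted.utr, model=model, flank=70)
best = scores[0]
print(f"\ndG_duplex = {best.dG_duplex:+.2f} kcal/mol  (hybridization)")
print(f"dG_open   = {best.dG_open:+.2f} kcal/mol  (site opening cost, >= 0)")
print(f"ddG       = {best.ddG:+.2f} kcal/mol  (total; lower = stronger)")

# the duplex itself, for comparison: miRNA vs its perfect complement region
site_seq = planted.utr[planted.site_start : planted.site_end]
dup = duplex_energy(MIR137_MATURE, site_seq, model)
print(f"\nduplex trace pairs {len(dup.pairs)} of {len(MIR137_MATURE)} mature bases "
      f"at {dup.energy:+.2f} kcal/mol")
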