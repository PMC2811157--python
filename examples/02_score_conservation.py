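"""Score the cross-species conservation of one phospho-site window.

Builds a small aligned family by hand (a conserved S-Q site with one or a
few flank substitutions per species), scores it, and prints the per-species
table row: window score on a 0-1 scale per species, the across-species mean
(column M) and the central-residue conservation rate (column N).
"""

from phosconet import OrthologFamily, PhosphoSiteRecord, score_site

seed = "MKRAVLEPLSQEYAGKERT"  # phospho-acceptor S at position 10, Q at +1
members = {
    ("H.sap", "variant1"): seed,
    ("M.mul", "variant1"): seed,                    # identical -> 1.0
    ("M.mus", "variant1"): "MKRAVLDPLSQEYAGKERT",   # 1 flank substitution -> 0.9
    ("R.nor", "variant1"): "MKRAVLDPLTQEYAGKERT",   # central S->T still conserved
    ("X.tro", "variant1"): "MKRCVADPLSQEYAGKERT",   # 2 subs inside the window -> 0.8
    ("D.rer", "variant1"): "MKRAVLEPLAQEYAGKERT",   # central S->A: score 0
}
family = OrthologFamily(protein_id="DEMO", members=members,
                        seed_key=("H.sap", "variant1"))
site = PhosphoSiteRecord("DEMO", 10, "S", known_kinases=("ATM",))

summary = score_site(family, site)
print(f"site {site.protein_id} {site.residue}{site.position}")
for species, score in summary.species_scores.items():
    if score.status != "numeric":
        print(f"  {species}: {score.status}")
    else:
        print(f"  {species}: {score.window_score:.3f} "
              f"(center conserved: {score.central_conserved})")
print(f"mean window conservation (M): {summary.mean_window_conservation:.3f}")
print(f"central conservation rate (N): {summary.central_conservation_rate:.3f}")
print("Species without an ortholog are NA and excluded from both aggregates; "
      "losing the central S/T forces that species' score to 0.")
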