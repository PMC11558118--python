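"""Convert critical forces into null-force binding free energies.

At the critical force F_c the observed binding and unbinding rates balance,
so the zero-force binding free energy is dG0 = -[F dx(F_c) - dG_stretch],
with the released 20-nt ssDNA described by a Marko-Siggia worm-like chain.
"""

from ssbwrap import WLCParams, binding_free_energy, delta_delta_g

wlc = WLCParams()  # Lp = 1.0 nm, 0.56 nm/nt, 300 K
print(f"WLC: Lp = {wlc.persistence_length} nm, "
      f"{wlc.contour_length_per_nt} nm/nt, kT = {wlc.kt:.4f} pN nm\n")

print(f"{'F_c (pN)':>9} {'work (kT)':>10} {'stretch (kT)':>13} {'dG0 (kT)':>9}")
for fc in (7.0, 10.0, 15.0):
    eb = delta_delta_g(fc, 20, wlc)
    dg0 = binding_free_energy(fc, 20, wlc)
    print(f"{fc:9.1f} {eb.work_term:10.2f} {eb.stretch_term:13.2f} {dg0:9.2f}")

# A larger critical force means the complex withstands more load, i.e.
# stronger (more negative) zero-force binding.
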