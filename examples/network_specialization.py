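"""Network- and species-level specialization of the survey web.

H2' standardizes the web's two-dimensional Shannon entropy between its
marginal-constrained extremes (0 = opportunistic, 1 = maximally
specialized); d' does the same per species with Kullback-Leibler host
selectivity; niche overlap averages Morisita-Horn similarity over all
insect pairs.  Significance comes from 100 Patefield randomizations
that hold both marginals fixed.
"""

from aroidnet import dprime, h2prime, mean_niche_overlap, null_ensemble, survey_web

web = survey_web()

h2p = h2prime(web)
no = mean_niche_overlap(web, "insects")
print(f"H2' = {h2p:.3f}   (survey printed 0.781)")
print(f"mean insect niche overlap NO = {no:.3f}   (survey printed 0.21)")

ens = null_ensemble(web, "H2prime", n=100, seed=42, tail="greater")
print(f"null model: mean {ens.null_mean:.4f}, sd {ens.null_sd:.5f}, "
      f"Z = {ens.z:.1f}, p = {ens.p_value:.3f} -> "
      f"{'highly significant' if ens.significant else 'not significant'}")

d = dprime(web, "insects").sort_values("d_prime", ascending=False)
print("\nmost host-selective insects (d'):")
print(d["d_prime"].head(8).round(3).to_string())
# d' near 1 marks species concentrated on hosts used by few others,
# e.g. the gall wasp confined to P. radiatum.
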