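"""Hand-checkable IVW on three instruments.

Three SNPs with exposure betas (0.1, 0.2, 0.15) and outcome betas
(0.02, 0.05, 0.03) at outcome SEs (0.01, 0.02, 0.015) have Wald ratios
0.2, 0.25, 0.2.  The inverse-variance-weighted combination is
sum(w*bx*by)/sum(w*bx^2) with w = 1/seY^2, and Cochran's Q measures how
much the three ratios disagree.
"""

from mrpipe import InstrumentSet, cochran_q, ivw, mr_egger

iset = InstrumentSet.from_arrays(
    beta_exp=[0.1, 0.2, 0.15],
    se_exp=[0.02, 0.02, 0.02],
    beta_out=[0.02, 0.05, 0.03],
    se_out=[0.01, 0.02, 0.015],
)

est = ivw(iset, model="fixed")
print(f"IVW beta  = {est.beta:.6f}  (expected 0.216667)")
print(f"IVW se    = {est.se:.6f}  (expected 0.057735)")
print(f"OR per SD = {est.or_:.4f}  (95% CI {est.or_ci_low:.4f}-{est.or_ci_high:.4f})")

q = cochran_q(iset)
print(f"Cochran Q = {q['q']:.4f} on {q['df']} df, p = {q['pval']:.4f}")

egger = mr_egger(iset)
print(f"Egger intercept = {egger.intercept.beta:.4f} "
      f"(p = {egger.intercept.pval:.3f}; near zero = no directional pleiotropy)")
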