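"""Fit the pattern component model and read off the Index of Similarity.

Simulates condition x voxel patterns with the protocol-dependent subcortical
covariance (between-movement correlation high at 2 mm, low at 1.5/3 mm),
fits G by EM, and prints the within-resolution IoS means: the 2 mm cells
come out least segregated (highest IoS), exactly as programmed.
"""

import numpy as np

import somatoseg as ss
from somatoseg.similarity import similarity_report

cells = ss.factorial_cells()
truth = ss.scenario_preset("subcortical_protocol_dependent")
Y = ss.simulate_patterns(truth.G_true, np.eye(9), v=2000, sigma2=0.5, seed=0)

fit = ss.fit_pcm_em(Y, np.eye(9), roi_name="putamen_left")
print(f"EM converged in {fit.n_iter} iterations, "
      f"loglik {fit.loglik:.1f}, sigma2_hat {fit.sigma2_hat:.3f}")

rep = similarity_report(fit, cells, n_eff=2000)
wr = rep.pairs[rep.pairs.family == "within_resolution"]
for res in (1.5, 2.0, 3.0):
    m = wr[wr.pair.str.contains(f"@{res:g}\\|")]["ios"].mean()
    print(f"mean within-resolution IoS at {res:g} mm: {m:.3f}")
print("(low IoS = well segregated; the 2 mm cells are the least segregated)")
n_sig = int(rep.tests["significant"].sum())
print(f"{n_sig} of {len(rep.tests)} pairwise IoS differences significant "
      f"after per-family FDR")
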