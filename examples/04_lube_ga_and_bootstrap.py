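"""The two non-gradient interval constructors: LUBE-GA and the bootstrap.

The LUBE loss multiplies normalized width by an exponential penalty on
coverage shortfall; it is non-differentiable, so a genetic algorithm
evolves the flattened network weights.  The bootstrap trains B point
regressors on resamples and combines model variance with an out-of-bag
noise variance into Gaussian intervals.
"""

import numpy as np

import painpi as pp
from painpi.bootstrap import BootstrapParams, bootstrap_pi
from painpi.losses import LossLParams
from painpi.train import GAParams, train_lube_ga

rng = np.random.default_rng(0)
train = pp.generate_known_quantile_regression(600, seed=3, alpha=0.15)
test = pp.generate_known_quantile_regression(600, seed=4, alpha=0.15)
X_tr, y_tr = train[["x"]].to_numpy(), train["y"].to_numpy()
X_te, y_te = test[["x"]].to_numpy(), test["y"].to_numpy()

net = pp.IntervalNet(1, (10,), seed=0)
net, trace = train_lube_ga(net, X_tr, y_tr,
                           LossLParams(eta=50, mu=0.85),
                           GAParams(n_generations=120, seed=0))
ga_batch = pp.predict_intervals(net, X_te, y_te)
print(f"LUBE-GA:   PICP {pp.picp(ga_batch):.3f}, "
      f"MPIW {pp.mpiw(ga_batch):.2f} "
      f"(best loss fell {trace['best_loss'].iloc[0]:.3f} -> "
      f"{trace['best_loss'].iloc[-1]:.3f})")

res = bootstrap_pi(X_tr, y_tr, X_te,
                   BootstrapParams(B=20, nominal=0.85, hidden_layers=(16,),
                                   epochs=80, seed=0))
bs_batch = res.as_batch(y_te)
print(f"bootstrap: PICP {pp.picp(bs_batch):.3f}, "
      f"MPIW {pp.mpiw(bs_batch):.2f} "
      f"(noise sd estimate {res.sigma_noise:.2f})")
print("\nBoth target 85% coverage; the GA evolves bounds directly while the")
print("bootstrap assumes Gaussian errors around an ensemble point estimate.")
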