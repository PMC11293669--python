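"""Train an interval network with the differentiable soft loss.

The network has two linear output heads (lower and upper bound) and is
trained by minibatch Adam on the soft loss: captured-only mean width plus
a quadratic penalty on the sigmoid-softened coverage shortfall.  The
problem here has known conditional quantiles, so the result can be read
against an exact oracle.
"""

import painpi as pp
from painpi.losses import LossSParams
from painpi.train import GDParams, train_soft_gd

train = pp.generate_known_quantile_regression(1000, seed=1, alpha=0.1)
test = pp.generate_known_quantile_regression(1000, seed=2, alpha=0.1)

net = pp.IntervalNet(input_dim=1, hidden_layers=(32, 32), seed=0)
net, trace = train_soft_gd(
    net, train[["x"]].to_numpy(), train["y"].to_numpy(),
    LossSParams(alpha=0.1),          # target 90% coverage
    GDParams(epochs=400, seed=0),
)

batch = pp.predict_intervals(net, test[["x"]].to_numpy(),
                             test["y"].to_numpy())
oracle = float((test["oracle_upper"] - test["oracle_lower"]).mean())
print(f"test PICP:  {pp.picp(batch):.3f}  (nominal 0.90)")
print(f"test MPIW:  {pp.mpiw(batch):.2f}  vs oracle width {oracle:.2f} "
      f"(ratio {pp.mpiw(batch) / oracle:.2f})")
print(f"final epoch training loss: {trace['loss'].iloc[-1]:.3f}")
print("\nCoverage near nominal with width close to the oracle's shows the")
print("loss is trading width against coverage as intended.")
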