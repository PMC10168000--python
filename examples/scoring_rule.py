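"""The disagreement-scoring rule, worked by hand.

When the four learners' votes are scattered (no label has 3 of 4 votes),
model N predicting class x scores

    N_score = F1_x^N * prod over dissenting models R voting y of
              (c + (1 - c) * P_R(y | x))

so a vote is strong when the model is reliable for that class (high F1) and
the other models' votes are the kind of mistake one would expect if x were
the true class (high P_R(y|x)).
"""

import numpy as np
import pandas as pd

from bioidkit import ScoreContext, ensemble_predict, score_model

classes = ["x", "y1", "y2"]
models = ["rf", "xgb", "mlp", "cart"]
f1 = {m: pd.Series([0.9, 0.8, 0.8], index=classes) for m in models}
mis = {m: pd.DataFrame(np.eye(3), index=classes, columns=classes) for m in models}
mis["xgb"].loc["x"] = [0.8, 0.2, 0.0]  # xgb confuses x with y1 20% of the time
ctx = ScoreContext(c=0.5, f1=f1, misclass=mis, macro_f1={m: 0.85 for m in models})

s = score_model("rf", "x", [("xgb", "y1"), ("mlp", "y2")], ctx)
print(f"score of rf voting 'x' against dissenters y1, y2: {s:.3f}")
print("  = F1 (0.9) * (0.5 + 0.5*0.2) * (0.5 + 0.5*0.0) = 0.27")

pred = ensemble_predict({"rf": "x", "xgb": "x", "mlp": "y1", "cart": "y2"}, ctx)
print(f"2-1-1 split resolved via {pred.path}: final label {pred.label!r}")
print({m: round(v, 3) for m, v in pred.scores.items()})
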