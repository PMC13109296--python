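"""The ordinal evaluation bundle on a hand-checkable example.

Six samples over three stages: OA counts the confusion-matrix diagonal,
kappa corrects it for chance agreement from the marginals, and the ordinal
MAE measures how many stages off the wrong predictions were.
"""

from phenodistill.metrics import evaluate

y_true = [1, 1, 2, 2, 3, 3]
y_pred = [1, 2, 2, 2, 3, 1]

report = evaluate(y_true, y_pred, n_stages=3)
print("confusion matrix (rows = true stage):")
print(report.matrix)
print(f"OA       {report.oa:.4f}   (4 of 6 on the diagonal)")
print(f"class-2 F1 {report.f1[1]:.4f} (precision 2/3, recall 1)")
print(f"kappa    {report.kappa:.4f}   (p0=2/3, pe=1/3)")
print(f"MAE      {report.mae:.4f}   (errors of 1 and 2 stages over 6 samples)")
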