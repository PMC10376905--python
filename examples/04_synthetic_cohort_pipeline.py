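"""The full workflow on a study-scale synthetic cohort.

Generates the default 15,977-variant cohort, encodes it, splits 70/30,
balances the training side, trains with fixed hyperparameters, and
prints held-out metrics plus the feature-importance ranking.
(Runs in about a minute; tuning is shown separately in example 02.)
"""

import myeloboost as mb

cohort = mb.generate_cohort(mb.CohortConfig(seed=0))
by_type = {t: sum(1 for r in cohort if r.variant_type == t)
           for t in ("SNV", "MNV", "INDEL")}
print(f"cohort: {len(cohort)} variants {by_type}, "
      f"{sum(r.label for r in cohort)} pathogenic")

table = mb.build_feature_table(cohort)
train, test = mb.stratified_split(table, mb.SplitSpec(seed=0))
balanced = mb.oversample_minority(train, seed=0)
counts = balanced["isMut"].value_counts().to_dict()
print(f"train {len(train)} rows -> balanced {counts}")

hp = mb.Hyperparameters(nrounds=400, eta_exponent=-1.5, max_depth=3,
                        gamma=0.2, colsample_bytree=0.9,
                        min_child_weight=1, subsample=0.9)
model = mb.train_final_model(balanced, hp, seed=0)

y = test["isMut"].astype(int).to_numpy()
scores = mb.predict_scores(model, test.drop(columns=["isMut"]))
cm = mb.confusion_counts(y, (scores >= 0.5).astype(int))
roc = mb.roc_auc(y, scores)
report = mb.classification_metrics(cm, auc=roc.auc)
pct = report.as_dict(percent=True)
print(f"\nheld-out ({len(test)} rows, original imbalance): "
      f"accuracy {pct['accuracy']:.2f}%  AUC {pct['auc']:.2f}%  "
      f"MCC {pct['mcc']:.2f}%  kappa {pct['kappa']:.2f}% "
      f"({mb.interpret_kappa(report.kappa)})")

importance = mb.feature_importance(model)
print("\nsplit-count feature importance (top 5):")
for _, row in importance.head(5).iterrows():
    print(f"  {row['feature']:>16}  {row['importance']:.3f}  "
          f"({row['scaled_0_100']:.1f}/100)")
top = importance.iloc[0]["feature"]
print(f"\nWith these fixed hyperparameters the most-split feature is "
      f"{top}; allele-frequency evidence (MAFbin, Freq) carries the "
      "bulk of the signal - absence of a population MAF, or a tiny "
      "value, is the strongest pathogenicity cue for somatic panel "
      "variants. Rankings among near-tied features shift with the "
      "model; tuned models (example 02) are what the validation suite "
      "checks.")
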