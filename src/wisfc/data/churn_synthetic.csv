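model_id,feature,importance,metric,performance
logistic_regression,tenure,0.92,abs_coefficient,0.79
logistic_regression,num_products,0.71,abs_coefficient,0.79
logistic_regression,credit_score,0.55,abs_coefficient,0.79
logistic_regression,balance,0.38,abs_coefficient,0.79
logistic_regression,online_usage,0.21,abs_coefficient,0.79
logistic_regression,age,0.09,abs_coefficient,0.79
decision_tree,tenure,0.34,impurity,0.81
decision_tree,credit_score,0.22,impurity,0.81
decision_tree,num_products,0.18,impurity,0.81
decision_tree,online_usage,0.12,impurity,0.81
decision_tree,balance,0.09,impurity,0.81
decision_tree,age,0.05,impurity,0.81
xgboost,age,0.30,gain,0.84
xgboost,tenure,0.25,gain,0.84
xgboost,balance,0.18,gain,0.84
xgboost,num_products,0.12,gain,0.84
xgboost,credit_score,0.09,gain,0.84
xgboost,online_usage,0.06,gain,0.84
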