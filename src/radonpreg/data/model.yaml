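# Compartment registry and directed transfer structure of the pregnancy radon
# model. `active_from` is the gestational day (days since conception) at which a
# compartment joins the system; maternal compartments are present throughout.
# Edge `source` names the parameterization that supplies the coefficient:
#   baseline        - constant, from baseline_rates.csv
#   maternal-table  - piecewise linear in gestational day, regressions_maternal.csv
#   fetal-table     - piecewise linear in gestational day, regressions_fetal.csv
# `interpreted: true` marks edges reconstructed from the prose description of
# lung gas exchange (air-blood equilibration) rather than from a tabulated value.
compartments:
  - {id: exhaled-air, group: sink, active_from: 0}
  - {id: lung-air, group: maternal, active_from: 0}
  - {id: arterial-blood, group: maternal, active_from: 0}
  - {id: venous-blood, group: maternal, active_from: 0}
  - {id: fat1, group: maternal, active_from: 0}
  - {id: fat2, group: maternal, active_from: 0}
  - {id: breast-g, group: maternal, active_from: 0}
  - {id: breast-a, group: maternal, active_from: 0}
  - {id: kidneys, group: maternal, active_from: 0}
  - {id: liver, group: maternal, active_from: 0}
  - {id: other, group: maternal, active_from: 0}
  - {id: uterus, group: maternal, active_from: 0}
  - {id: placenta, group: exchange, active_from: 105}
  - {id: venous-cord-blood, group: exchange, active_from: 105}
  - {id: arterial-cord-blood, group: exchange, active_from: 105}
  - {id: fetal-lungs, group: fetal, active_from: 105}
  - {id: fetal-brain, group: fetal, active_from: 105}
  - {id: fetal-kidneys, group: fetal, active_from: 105}
  - {id: fetal-bone, group: fetal, active_from: 105}
  - {id: fetal-liver, group: fetal, active_from: 105}
  - {id: fetal-thyroid, group: fetal, active_from: 126}
  - {id: fetal-bone-marrow, group: fetal, active_from: 126}
  - {id: fetal-other, group: fetal, active_from: 126}
  - {id: fetal-adipose, group: fetal, active_from: 161}
edges:
  - {from: lung-air, to: exhaled-air, source: baseline, interpreted: true}
  - {from: lung-air, to: arterial-blood, source: baseline, interpreted: true}
  - {from: venous-blood, to: lung-air, source: baseline, interpreted: true}
  - {from: venous-blood, to: arterial-blood, source: baseline, interpreted: true}
  - {from: arterial-blood, to: liver, source: baseline}
  - {from: arterial-blood, to: other, source: baseline}
  - {from: liver, to: venous-blood, source: baseline}
  - {from: other, to: venous-blood, source: baseline}
  - {from: other, to: liver, source: baseline}
  - {from: arterial-blood, to: uterus, source: maternal-table}
  - {from: uterus, to: venous-blood, source: maternal-table}
  - {from: arterial-blood, to: fat1, source: maternal-table}
  - {from: fat1, to: venous-blood, source: maternal-table}
  - {from: arterial-blood, to: fat2, source: maternal-table}
  - {from: fat2, to: venous-blood, source: maternal-table}
  - {from: arterial-blood, to: breast-g, source: maternal-table}
  - {from: breast-g, to: venous-blood, source: maternal-table}
  - {from: arterial-blood, to: breast-a, source: maternal-table}
  - {from: breast-a, to: venous-blood, source: maternal-table}
  - {from: arterial-blood, to: kidneys, source: maternal-table}
  - {from: kidneys, to: venous-blood, source: maternal-table}
  - {from: uterus, to: placenta, source: fetal-table}
  - {from: placenta, to: uterus, source: fetal-table}
  - {from: placenta, to: venous-cord-blood, source: fetal-table}
  - {from: arterial-cord-blood, to: placenta, source: fetal-table}
  - {from: venous-cord-blood, to: fetal-lungs, source: fetal-table}
  - {from: venous-cord-blood, to: fetal-brain, source: fetal-table}
  - {from: venous-cord-blood, to: fetal-kidneys, source: fetal-table}
  - {from: venous-cord-blood, to: fetal-thyroid, source: fetal-table}
  - {from: venous-cord-blood, to: fetal-bone, source: fetal-table}
  - {from: venous-cord-blood, to: fetal-bone-marrow, source: fetal-table}
  - {from: venous-cord-blood, to: fetal-liver, source: fetal-table}
  - {from: venous-cord-blood, to: fetal-other, source: fetal-table}
  - {from: venous-cord-blood, to: fetal-adipose, source: fetal-table}
  - {from: fetal-lungs, to: arterial-cord-blood, source: fetal-table}
  - {from: fetal-brain, to: arterial-cord-blood, source: fetal-table}
  - {from: fetal-kidneys, to: arterial-cord-blood, source: fetal-table}
  - {from: fetal-adipose, to: arterial-cord-blood, source: fetal-table}
  - {from: fetal-thyroid, to: arterial-cord-blood, source: fetal-table}
  - {from: fetal-bone, to: arterial-cord-blood, source: fetal-table}
  - {from: fetal-bone-marrow, to: arterial-cord-blood, source: fetal-table}
  - {from: fetal-liver, to: arterial-cord-blood, source: fetal-table}
  - {from: fetal-other, to: arterial-cord-blood, source: fetal-table}
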