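{
  "_comment": "Synthetic demonstration haplotype-frequency table for the cPRA engine. Two invented populations; haplotypes are specified as serologic base antigens (A/B/Cw/DR/DQ plus linked DR51/52/53). These are NOT registry frequencies.",
  "mode": "haplotype",
  "populations": [
    {
      "name": "synthetic_pop_1",
      "weight": 0.6,
      "haplotypes": [
        {"antigens": ["A1", "B8", "Cw7", "DR17", "DR52", "DQ2"], "frequency": 0.14},
        {"antigens": ["A2", "B44", "Cw5", "DR4", "DR53", "DQ8"], "frequency": 0.16},
        {"antigens": ["A3", "B7", "Cw7", "DR15", "DR51", "DQ6"], "frequency": 0.15},
        {"antigens": ["A2", "B7", "Cw7", "DR15", "DR51", "DQ6"], "frequency": 0.05},
        {"antigens": ["A1", "B57", "Cw6", "DR7", "DR53", "DQ9"], "frequency": 0.08},
        {"antigens": ["A24", "B35", "Cw4", "DR11", "DR52", "DQ7"], "frequency": 0.10},
        {"antigens": ["A26", "B38", "Cw12", "DR13", "DR52", "DQ6"], "frequency": 0.08},
        {"antigens": ["A2", "B60", "Cw10", "DR13", "DR52", "DQ6"], "frequency": 0.10},
        {"antigens": ["A11", "B27", "Cw1", "DR1", "DQ5"], "frequency": 0.08},
        {"antigens": ["A29", "B44", "Cw16", "DR7", "DR53", "DQ2"], "frequency": 0.06}
      ]
    },
    {
      "name": "synthetic_pop_2",
      "weight": 0.4,
      "haplotypes": [
        {"antigens": ["A30", "B42", "Cw17", "DR18", "DR52", "DQ4"], "frequency": 0.12},
        {"antigens": ["A2", "B53", "Cw4", "DR11", "DR52", "DQ7"], "frequency": 0.15},
        {"antigens": ["A23", "B45", "Cw6", "DR7", "DR53", "DQ2"], "frequency": 0.10},
        {"antigens": ["A68", "B58", "Cw6", "DR12", "DR52", "DQ7"], "frequency": 0.10},
        {"antigens": ["A3", "B7", "Cw7", "DR15", "DR51", "DQ6"], "frequency": 0.08},
        {"antigens": ["A36", "B53", "Cw4", "DR11", "DR52", "DQ7"], "frequency": 0.07},
        {"antigens": ["A2", "B62", "Cw9", "DR4", "DR53", "DQ8"], "frequency": 0.10},
        {"antigens": ["A33", "B65", "Cw8", "DR13", "DR52", "DQ6"], "frequency": 0.08},
        {"antigens": ["A74", "B35", "Cw4", "DR13", "DR52", "DQ6"], "frequency": 0.10},
        {"antigens": ["A1", "B8", "Cw7", "DR17", "DR52", "DQ2"], "frequency": 0.10}
      ]
    }
  ]
}
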