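{
 "name": "expert_risk_default",
 "inputs": [
  {
   "name": "sensors_score",
   "range": [
    0.0,
    10.0
   ],
   "labels": [
    {
     "name": "Low",
     "knots": [
      0.0,
      0.0,
      3.0,
      5.0
     ]
    },
    {
     "name": "Medium",
     "knots": [
      3.0,
      4.5,
      5.5,
      7.0
     ]
    },
    {
     "name": "High",
     "knots": [
      5.0,
      7.0,
      10.0,
      10.0
     ]
    }
   ]
  },
  {
   "name": "history_score",
   "range": [
    0.0,
    10.0
   ],
   "labels": [
    {
     "name": "Low",
     "knots": [
      0.0,
      0.0,
      3.0,
      5.0
     ]
    },
    {
     "name": "Medium",
     "knots": [
      3.0,
      4.5,
      5.5,
      7.0
     ]
    },
    {
     "name": "High",
     "knots": [
      5.0,
      7.0,
      10.0,
      10.0
     ]
    }
   ]
  },
  {
   "name": "other_factors_score",
   "range": [
    0.0,
    10.0
   ],
   "labels": [
    {
     "name": "Low",
     "knots": [
      0.0,
      0.0,
      3.0,
      5.0
     ]
    },
    {
     "name": "Medium",
     "knots": [
      3.0,
      4.5,
      5.5,
      7.0
     ]
    },
    {
     "name": "High",
     "knots": [
      5.0,
      7.0,
      10.0,
      10.0
     ]
    }
   ]
  }
 ],
 "output": {
  "name": "expert_risk",
  "range": [
   0.0,
   100.0
  ],
  "labels": [
   {
    "name": "R1",
    "knots": [
     0.0,
     0.0,
     20.0,
     20.0
    ]
   },
   {
    "name": "R2",
    "knots": [
     18.0,
     27.0,
     33.0,
     42.0
    ]
   },
   {
    "name": "R3",
    "knots": [
     38.0,
     47.0,
     53.0,
     62.0
    ]
   },
   {
    "name": "R4",
    "knots": [
     58.0,
     67.0,
     73.0,
     82.0
    ]
   },
   {
    "name": "R5",
    "knots": [
     80.0,
     80.0,
     100.0,
     100.0
    ]
   }
  ]
 },
 "rules": [
  {
   "if": {
    "sensors_score": "Low",
    "history_score": "Low",
    "other_factors_score": "Low"
   },
   "then": "R1"
  },
  {
   "if": {
    "sensors_score": "Low",
    "history_score": "Low",
    "other_factors_score": "Medium"
   },
   "then": "R3"
  },
  {
   "if": {
    "sensors_score": "Low",
    "history_score": "Low",
    "other_factors_score": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "Low",
    "history_score": "Medium",
    "other_factors_score": "Low"
   },
   "then": "R3"
  },
  {
   "if": {
    "sensors_score": "Low",
    "history_score": "Medium",
    "other_factors_score": "Medium"
   },
   "then": "R3"
  },
  {
   "if": {
    "sensors_score": "Low",
    "history_score": "Medium",
    "other_factors_score": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "Low",
    "history_score": "High",
    "other_factors_score": "Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "Low",
    "history_score": "High",
    "other_factors_score": "Medium"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "Low",
    "history_score": "High",
    "other_factors_score": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "Medium",
    "history_score": "Low",
    "other_factors_score": "Low"
   },
   "then": "R1"
  },
  {
   "if": {
    "sensors_score": "Medium",
    "history_score": "Low",
    "other_factors_score": "Medium"
   },
   "then": "R3"
  },
  {
   "if": {
    "sensors_score": "Medium",
    "history_score": "Low",
    "other_factors_score": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "Medium",
    "history_score": "Medium",
    "other_factors_score": "Low"
   },
   "then": "R3"
  },
  {
   "if": {
    "sensors_score": "Medium",
    "history_score": "Medium",
    "other_factors_score": "Medium"
   },
   "then": "R3"
  },
  {
   "if": {
    "sensors_score": "Medium",
    "history_score": "Medium",
    "other_factors_score": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "Medium",
    "history_score": "High",
    "other_factors_score": "Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "Medium",
    "history_score": "High",
    "other_factors_score": "Medium"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "Medium",
    "history_score": "High",
    "other_factors_score": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "High",
    "history_score": "Low",
    "other_factors_score": "Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "High",
    "history_score": "Low",
    "other_factors_score": "Medium"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "High",
    "history_score": "Low",
    "other_factors_score": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "High",
    "history_score": "Medium",
    "other_factors_score": "Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "High",
    "history_score": "Medium",
    "other_factors_score": "Medium"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "High",
    "history_score": "Medium",
    "other_factors_score": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "High",
    "history_score": "High",
    "other_factors_score": "Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "High",
    "history_score": "High",
    "other_factors_score": "Medium"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "High",
    "history_score": "High",
    "other_factors_score": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "sensors_score": "Medium",
    "history_score": "Low",
    "other_factors_score": "Low"
   },
   "then": "R1"
  },
  {
   "if": {
    "sensors_score": "Low",
    "history_score": "High",
    "other_factors_score": "High"
   },
   "then": "R5"
  }
 ],
 "resolution": 1001
}
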