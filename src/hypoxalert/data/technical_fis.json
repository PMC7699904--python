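{
 "name": "technical_risk_default",
 "inputs": [
  {
   "name": "spo2",
   "range": [
    70.0,
    100.0
   ],
   "labels": [
    {
     "name": "Very_Low",
     "knots": [
      70.0,
      70.0,
      75.0,
      80.0
     ]
    },
    {
     "name": "Low",
     "knots": [
      75.0,
      80.0,
      90.0,
      97.0
     ]
    },
    {
     "name": "Normal",
     "knots": [
      90.0,
      97.0,
      100.0,
      100.0
     ]
    }
   ]
  },
  {
   "name": "temperature",
   "range": [
    33.0,
    41.0
   ],
   "labels": [
    {
     "name": "Low",
     "knots": [
      33.0,
      33.0,
      35.0,
      36.2
     ]
    },
    {
     "name": "Normal",
     "knots": [
      35.0,
      36.0,
      36.5,
      37.349999999999994
     ]
    },
    {
     "name": "High",
     "knots": [
      36.5,
      38.199999999999996,
      41.0,
      41.0
     ]
    }
   ]
  },
  {
   "name": "heart_rate",
   "range": [
    15.0,
    180.0
   ],
   "labels": [
    {
     "name": "Very_Low",
     "knots": [
      15.0,
      15.0,
      35.0,
      45.0
     ]
    },
    {
     "name": "Low",
     "knots": [
      35.0,
      45.0,
      55.0,
      65.0
     ]
    },
    {
     "name": "Normal",
     "knots": [
      55.0,
      65.0,
      95.0,
      110.0
     ]
    },
    {
     "name": "High",
     "knots": [
      95.0,
      110.0,
      130.0,
      150.0
     ]
    },
    {
     "name": "Very_High",
     "knots": [
      130.0,
      150.0,
      180.0,
      180.0
     ]
    }
   ]
  }
 ],
 "output": {
  "name": "technical_risk",
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
    "spo2": "Very_Low",
    "temperature": "Low",
    "heart_rate": "Very_Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "Low",
    "heart_rate": "Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "Low",
    "heart_rate": "Normal"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "Low",
    "heart_rate": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "Low",
    "heart_rate": "Very_High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "Normal",
    "heart_rate": "Very_Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "Normal",
    "heart_rate": "Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "Normal",
    "heart_rate": "Normal"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "Normal",
    "heart_rate": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "Normal",
    "heart_rate": "Very_High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "High",
    "heart_rate": "Very_Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "High",
    "heart_rate": "Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "High",
    "heart_rate": "Normal"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "High",
    "heart_rate": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Very_Low",
    "temperature": "High",
    "heart_rate": "Very_High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "Low",
    "heart_rate": "Very_Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "Low",
    "heart_rate": "Low"
   },
   "then": "R3"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "Low",
    "heart_rate": "Normal"
   },
   "then": "R3"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "Low",
    "heart_rate": "High"
   },
   "then": "R3"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "Low",
    "heart_rate": "Very_High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "Normal",
    "heart_rate": "Very_Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "Normal",
    "heart_rate": "Low"
   },
   "then": "R3"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "Normal",
    "heart_rate": "Normal"
   },
   "then": "R1"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "Normal",
    "heart_rate": "High"
   },
   "then": "R1"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "Normal",
    "heart_rate": "Very_High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "High",
    "heart_rate": "Very_Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "High",
    "heart_rate": "Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "High",
    "heart_rate": "Normal"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "High",
    "heart_rate": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Low",
    "temperature": "High",
    "heart_rate": "Very_High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "Low",
    "heart_rate": "Very_Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "Low",
    "heart_rate": "Low"
   },
   "then": "R3"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "Low",
    "heart_rate": "Normal"
   },
   "then": "R3"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "Low",
    "heart_rate": "High"
   },
   "then": "R3"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "Low",
    "heart_rate": "Very_High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "Normal",
    "heart_rate": "Very_Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "Normal",
    "heart_rate": "Low"
   },
   "then": "R3"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "Normal",
    "heart_rate": "Normal"
   },
   "then": "R1"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "Normal",
    "heart_rate": "High"
   },
   "then": "R1"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "Normal",
    "heart_rate": "Very_High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "High",
    "heart_rate": "Very_Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "High",
    "heart_rate": "Low"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "High",
    "heart_rate": "Normal"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "High",
    "heart_rate": "High"
   },
   "then": "R5"
  },
  {
   "if": {
    "spo2": "Normal",
    "temperature": "High",
    "heart_rate": "Very_High"
   },
   "then": "R5"
  }
 ],
 "resolution": 1001
}
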