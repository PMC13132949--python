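{
 "age_coding": "completed",
 "name": "danish_2025",
 "percentiles": [
  50,
  90,
  95
 ],
 "provenance": "Age- and sex-specific 50th/90th/95th percentile oscillometric office BP reference values (mmHg), Danish children aged 4-15, supine, Welch Allyn Pro-BP-3400.",
 "type": "lookup",
 "values": {
  "dbp": {
   "F": {
    "10": {
     "50": 65,
     "90": 72,
     "95": 73
    },
    "11": {
     "50": 66,
     "90": 73,
     "95": 74
    },
    "12": {
     "50": 66,
     "90": 73,
     "95": 74
    },
    "13": {
     "50": 66,
     "90": 73,
     "95": 75
    },
    "14": {
     "50": 67,
     "90": 74,
     "95": 75
    },
    "15": {
     "50": 67,
     "90": 74,
     "95": 76
    },
    "4": {
     "50": 62,
     "90": 69,
     "95": 70
    },
    "5": {
     "50": 63,
     "90": 69,
     "95": 71
    },
    "6": {
     "50": 63,
     "90": 70,
     "95": 71
    },
    "7": {
     "50": 64,
     "90": 70,
     "95": 72
    },
    "8": {
     "50": 64,
     "90": 71,
     "95": 72
    },
    "9": {
     "50": 65,
     "90": 71,
     "95": 73
    }
   },
   "M": {
    "10": {
     "50": 64,
     "90": 70,
     "95": 72
    },
    "11": {
     "50": 65,
     "90": 71,
     "95": 72
    },
    "12": {
     "50": 65,
     "90": 71,
     "95": 73
    },
    "13": {
     "50": 65,
     "90": 71,
     "95": 73
    },
    "14": {
     "50": 66,
     "90": 72,
     "95": 74
    },
    "15": {
     "50": 66,
     "90": 72,
     "95": 74
    },
    "4": {
     "50": 61,
     "90": 67,
     "95": 69
    },
    "5": {
     "50": 62,
     "90": 68,
     "95": 69
    },
    "6": {
     "50": 62,
     "90": 68,
     "95": 70
    },
    "7": {
     "50": 63,
     "90": 69,
     "95": 70
    },
    "8": {
     "50": 63,
     "90": 69,
     "95": 71
    },
    "9": {
     "50": 64,
     "90": 70,
     "95": 71
    }
   }
  },
  "sbp": {
   "F": {
    "10": {
     "50": 104,
     "90": 114,
     "95": 116
    },
    "11": {
     "50": 105,
     "90": 115,
     "95": 118
    },
    "12": {
     "50": 107,
     "90": 117,
     "95": 120
    },
    "13": {
     "50": 109,
     "90": 119,
     "95": 121
    },
    "14": {
     "50": 110,
     "90": 120,
     "95": 123
    },
    "15": {
     "50": 111,
     "90": 122,
     "95": 124
    },
    "4": {
     "50": 96,
     "90": 104,
     "95": 107
    },
    "5": {
     "50": 97,
     "90": 105,
     "95": 108
    },
    "6": {
     "50": 99,
     "90": 107,
     "95": 110
    },
    "7": {
     "50": 100,
     "90": 109,
     "95": 112
    },
    "8": {
     "50": 101,
     "90": 110,
     "95": 113
    },
    "9": {
     "50": 103,
     "90": 112,
     "95": 115
    }
   },
   "M": {
    "10": {
     "50": 104,
     "90": 114,
     "95": 118
    },
    "11": {
     "50": 105,
     "90": 116,
     "95": 119
    },
    "12": {
     "50": 107,
     "90": 117,
     "95": 121
    },
    "13": {
     "50": 108,
     "90": 119,
     "95": 122
    },
    "14": {
     "50": 109,
     "90": 120,
     "95": 124
    },
    "15": {
     "50": 111,
     "90": 122,
     "95": 126
    },
    "4": {
     "50": 96,
     "90": 104,
     "95": 109
    },
    "5": {
     "50": 97,
     "90": 106,
     "95": 110
    },
    "6": {
     "50": 99,
     "90": 107,
     "95": 111
    },
    "7": {
     "50": 100,
     "90": 109,
     "95": 113
    },
    "8": {
     "50": 101,
     "90": 111,
     "95": 114
    },
    "9": {
     "50": 103,
     "90": 112,
     "95": 116
    }
   }
  }
 }
}
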