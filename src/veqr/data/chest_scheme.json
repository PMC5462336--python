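{
 "labels": {
  "1": "trachea",
  "2": "main_bronchus_left",
  "3": "main_bronchus_right",
  "4": "lung_left",
  "5": "lung_right",
  "6": "heart",
  "7": "aorta",
  "8": "pulmonary_trunk",
  "10": "rib_left_01",
  "11": "rib_left_02",
  "12": "rib_left_03",
  "13": "rib_left_04",
  "14": "rib_left_05",
  "15": "rib_left_06",
  "16": "rib_left_07",
  "17": "rib_left_08",
  "18": "rib_left_09",
  "19": "rib_left_10",
  "20": "rib_left_11",
  "21": "rib_left_12",
  "22": "rib_right_01",
  "23": "rib_right_02",
  "24": "rib_right_03",
  "25": "rib_right_04",
  "26": "rib_right_05",
  "27": "rib_right_06",
  "28": "rib_right_07",
  "29": "rib_right_08",
  "30": "rib_right_09",
  "31": "rib_right_10",
  "32": "rib_right_11",
  "33": "rib_right_12",
  "40": "vertebra_01",
  "41": "vertebra_02",
  "42": "vertebra_03",
  "43": "vertebra_04",
  "44": "vertebra_05",
  "45": "vertebra_06",
  "46": "vertebra_07",
  "47": "vertebra_08",
  "48": "vertebra_09",
  "49": "vertebra_10",
  "50": "vertebra_11",
  "51": "vertebra_12",
  "52": "vertebra_13",
  "53": "vertebra_14",
  "54": "vertebra_15",
  "60": "skin",
  "61": "breast_left",
  "62": "breast_right"
 },
 "regions": {
  "airway": [
   1,
   2,
   3
  ],
  "lung": [
   4,
   5
  ],
  "cardiac region": [
   6,
   7,
   8
  ],
  "rib": [
   10,
   11,
   12,
   13,
   14,
   15,
   16,
   17,
   18,
   19,
   20,
   21,
   22,
   23,
   24,
   25,
   26,
   27,
   28,
   29,
   30,
   31,
   32,
   33
  ],
  "vertebra": [
   40,
   41,
   42,
   43,
   44,
   45,
   46,
   47,
   48,
   49,
   50,
   51,
   52,
   53,
   54
  ],
  "skin": [
   60
  ],
  "breast": [
   61,
   62
  ]
 },
 "background": 0,
 "no_data": 65535,
 "grade_levels": {
  "lung": 2,
  "skin": 2,
  "airway": 3,
  "cardiac region": 3,
  "rib": 3,
  "vertebra": 3,
  "breast": 3
 }
}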