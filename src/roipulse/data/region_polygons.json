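{
 "0": [
  0,
  1,
  2,
  3
 ],
 "1": [
  4,
  5,
  6,
  7
 ],
 "2": [
  8,
  9,
  10,
  11
 ],
 "3": [
  12,
  13,
  14,
  15
 ],
 "4": [
  16,
  17,
  18,
  19
 ],
 "5": [
  20,
  21,
  22,
  23
 ],
 "6": [
  24,
  25,
  26,
  27
 ],
 "7": [
  28,
  29,
  30,
  31
 ],
 "8": [
  32,
  33,
  34,
  35
 ],
 "9": [
  36,
  37,
  38,
  39
 ],
 "10": [
  40,
  41,
  42,
  43
 ],
 "11": [
  44,
  45,
  46,
  47
 ],
 "12": [
  48,
  49,
  50,
  51
 ],
 "13": [
  52,
  53,
  54,
  55
 ],
 "14": [
  56,
  57,
  58,
  59
 ],
 "15": [
  60,
  61,
  62,
  63
 ],
 "16": [
  64,
  65,
  66,
  67
 ],
 "17": [
  68,
  69,
  70,
  71
 ],
 "18": [
  72,
  73,
  74,
  75
 ],
 "19": [
  76,
  77,
  78,
  79
 ],
 "20": [
  80,
  81,
  82,
  83
 ],
 "21": [
  84,
  85,
  86,
  87
 ],
 "22": [
  88,
  89,
  90,
  91
 ],
 "23": [
  92,
  93,
  94,
  95
 ],
 "24": [
  96,
  97,
  98,
  99
 ],
 "25": [
  100,
  101,
  102,
  103
 ],
 "26": [
  104,
  105,
  106,
  107
 ],
 "27": [
  108,
  109,
  110,
  111
 ],
 "28": [
  112,
  113,
  114,
  115
 ],
 "29": [
  116,
  117,
  118,
  119
 ],
 "30": [
  120,
  121,
  122,
  123
 ]
}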