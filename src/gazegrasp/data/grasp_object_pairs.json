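{
  "version": 1,
  "description": "Pairing between the 10 grasp types and the 18 household objects of the grasping protocol; each grasp is performed on exactly three objects.",
  "pairs": {
    "medium wrap": ["bottle", "can", "door handle"],
    "lateral": ["mug", "key", "pencil case"],
    "parallel extension": ["plate", "book", "drawer"],
    "tripod grasp": ["bottle", "mug", "drawer"],
    "power sphere": ["ball", "bulb", "key"],
    "precision disk": ["jar", "bulb", "ball"],
    "prismatic pinch": ["clothespin", "key", "can"],
    "index finger extension": ["remote", "knife", "fork"],
    "adducted thumb": ["screwdriver", "remote", "wrench"],
    "prismatic four finger": ["knife", "fork", "wrench"]
  }
}
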