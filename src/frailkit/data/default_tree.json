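{
 "item": "badl_help_count",
 "op": ">=",
 "value": 3,
 "children": {
  "yes": {"cfs": 7},
  "no": {
   "item": "badl_help_count",
   "op": ">=",
   "value": 1,
   "children": {
    "yes": {"cfs": 6},
    "no": {
     "item": "iadl_help_count",
     "op": ">=",
     "value": 1,
     "children": {
      "yes": {"cfs": 5},
      "no": {
       "item": "effort_frequency",
       "op": "in",
       "value": ["occasional", "all"],
       "children": {
        "yes": {"cfs": 4},
        "no": {
         "item": "self_rated_health",
         "op": "in",
         "value": ["fair", "poor"],
         "children": {
          "yes": {"cfs": 4},
          "no": {
           "item": "active_past_week",
           "op": "==",
           "value": true,
           "children": {
            "yes": {
             "item": "condition_count",
             "op": "<=",
             "value": 1,
             "children": {
              "yes": {
               "item": "self_rated_health",
               "op": "in",
               "value": ["excellent", "very good"],
               "children": {
                "yes": {"cfs": 1},
                "no": {"cfs": 2}
               }
              },
              "no": {"cfs": 2}
             }
            },
            "no": {"cfs": 3}
           }
          }
         }
        }
       }
      }
     }
    }
   }
  }
 }
}
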