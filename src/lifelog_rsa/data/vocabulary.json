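{
  "version": "1.0",
  "description": "Lifelog episode tag vocabulary: 16 places + 22 activities + 13 people + the catch-all 'other' tag (52 tags total).",
  "categories": {
    "places": [
      "Outdoor",
      "Airport/Bus-station",
      "Gas station",
      "Park/Museum/Zoo",
      "Gym",
      "Library",
      "Parents'/siblings'/relatives' home or apartment",
      "Mall",
      "Friend's home/apartment",
      "Class/meeting room/hall",
      "Restaurant/Cafe/Bar",
      "My office/lab/workplace",
      "Home/apartment",
      "Other office",
      "Store",
      "Other person's office/workplace"
    ],
    "activities": [
      "Chores",
      "Thinking",
      "Party",
      "Talk on phone",
      "Use a computer",
      "Exercise",
      "Shopping",
      "Personal hygiene",
      "Relax",
      "Eat/drink",
      "Talk/chat with other(s)",
      "Phone not worn",
      "Study",
      "Work",
      "Drive",
      "Care for/play with child/baby",
      "Ride bike",
      "Giving a lecture/presentation",
      "Listening to a lecture/presentation",
      "Walk",
      "Sit in a vehicle",
      "Hobbies"
    ],
    "people": [
      "Kids",
      "Family",
      "Friends/Classmates",
      "Pet",
      "Salesperson/Clerk/Cashier",
      "Boyfriend/Girlfriend",
      "Stranger",
      "Alone",
      "Professor (of my classes)",
      "Student",
      "Spouse/Partner",
      "Crowd (in a public place)",
      "Work colleagues"
    ],
    "other": [
      "other"
    ]
  }
}
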